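"""Continuous re-anchoring when switching between reference frames.

When an agent swaps between egocentric and allocentric representations,
the new frame's zero is set to the current heading and the ring state is
circularly shifted so the activity bump keeps encoding the same world
direction (to within one neuron spacing, 2*pi/Ns).  Without that shift a
switch would make the same bump drive motion in a different direction.
"""

import numpy as np

import ringflock as rf
from ringflock.geometry import circ_dist, ring_angles
from ringflock.spin import bump_states

NS = 100
agent = rf.Agent(
    id=0, position=np.array([500.0, 500.0]), heading=2.1,
    velocity=np.zeros(2), frame=rf.Frame("allo", origin=0.4),
    network=rf.SpinRingNetwork(NS, beta=400.0,
                               states=bump_states(NS, 30, 50)),
    v0=10.0)

def world_direction(a):
    v = a.network.velocity(a.frame.origin + ring_angles(NS), a.v0)
    return np.arctan2(v[1], v[0]) % (2 * np.pi)

before = world_direction(agent)
rf.apply_frame_switch(agent, "ego")
after = world_direction(agent)
jump = circ_dist(before, after)
print(f"readout direction before switch: {before:.4f} rad")
print(f"readout direction after switch : {after:.4f} rad")
print(f"change: {jump:.4f} rad  (<= one neuron spacing "
      f"2*pi/Ns = {2 * np.pi / NS:.4f})")
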