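"""Emergence of collective motion: allocentric vs egocentric populations.

Twenty spin-model agents attract each other (total social attraction
h_t^s = 0.1) in the ordered network regime.  With allocentric bearings the
group reaches high global order (polarized collective motion); with
egocentric bearings agents align only locally and the group stays globally
disordered.
"""

import numpy as np

import ringflock as rf
from ringflock.metrics import global_order_series, local_order_series

for frame in ("allo", "ego"):
    cfg = rf.SimulationConfig(
        model="spin", frame_policy=frame, N=20, Ns=100, beta=400.0,
        steps=3000, seed=2, record_every=5,
        coupling=rf.SocialCoupling(h_t_s=0.1))
    rec = rf.run_simulation(cfg)
    go = global_order_series(rec)
    lo = local_order_series(rec)
    tail = slice(2 * len(go) // 3, None)
    print(f"{frame:4s}: global order = {go[tail].mean():.2f}, "
          f"local order = {lo[tail].mean():.2f}  (time-averaged last third)")

print("\nHigh GO only for the allocentric population; the egocentric one "
      "shows local alignment (high LO) without global order.")
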