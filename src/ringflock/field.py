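"""Neural-field (Amari-type) ring attractor.

Membrane potentials ``u_i`` on the same modified-cosine ring evolve by the
Euler-discretized field dynamics

    u_i(t + dt) = u_i(t) + dt * [ -u_i + (1/Ns) * sum_j J_ij tanh(beta u_j)
                                  - h_b + h_i ],

with tanh output of slope beta (sharper output = less noisy dynamics).  The
dynamics are deterministic; all stochasticity enters through the initial
condition and, in the embodied loop, through frame switching.  The movement
readout rectifies the output: only positively active neurons contribute,

    v = (v0/Ns) * sum_i max(0, tanh(beta u_i)) * (cos c_i, sin c_i),

so both direction and speed are shaped by the bump.  A constant-speed
variant reads out only the heading from the rectified population vector.

Unlike the spin model's sensory field, the Gaussian here carries no
normalizing prefactor; the two conventions are implemented exactly as they
differ, not unified.
"""

from __future__ import annotations

import numpy as np

from .geometry import circ_dist, wrap_angle
from .spin import build_connectivity

__all__ = [
    "field_output",
    "field_sensory_field",
    "FieldRingNetwork",
]


def field_output(u, beta: float) -> np.ndarray:
    """Neuron output ``F_i = tanh(beta * u_i)``, in (-1, 1), odd in u."""
    return np.tanh(beta * np.asarray(u, dtype=float))


def field_sensory_field(centers, sources, sigma: float) -> np.ndarray:
    """Unnormalized-Gaussian sensory field: each source ``(bearing, amp)``
    contributes ``amp * exp(-circ_dist(center, bearing)^2 / (2 sigma^2))``."""
    if not sigma > 0:
        raise ValueError(f"receptive width sigma must be positive, got {sigma}")
    centers = np.asarray(centers, dtype=float)
    h = np.zeros_like(centers)
    for bearing, amplitude in sources:
        d = circ_dist(centers, bearing)
        h += amplitude * np.exp(-(d**2) / (2.0 * sigma**2))
    return h


class FieldRingNetwork:
    """One discretized neural-field ring.

    Parameters mirror the spin network where they overlap; ``dt`` is the
    Euler step (one step per simulation timestep), and ``beta`` is the tanh
    output slope.  ``zero_recurrence=True`` removes the recurrent kernel
    (J_ij = 0 for all pairs) while keeping every other part of the dynamics,
    leaving a purely feedforward network.
    """

    def __init__(self, n_s, beta, nu=0.5, h_b=0.0, dt=0.3, u=None,
                 connectivity=None, zero_recurrence=False):
        if not beta > 0:
            raise ValueError(f"output slope beta must be positive, got {beta}")
        if not 0 < dt:
            raise ValueError(f"Euler step dt must be positive, got {dt}")
        self.n_s = int(n_s)
        self.beta = float(beta)
        self.nu = float(nu)
        self.h_b = float(h_b)
        self.dt = float(dt)
        if zero_recurrence:
            self.J = np.zeros((self.n_s, self.n_s))
        elif connectivity is None:
            self.J = build_connectivity(self.n_s, self.nu)
        else:
            self.J = np.asarray(connectivity, dtype=float)
        self.u = np.zeros(self.n_s) if u is None else np.asarray(u, dtype=float).copy()
        if self.u.shape != (self.n_s,):
            raise ValueError("u must be a length-Ns vector")

    def output(self) -> np.ndarray:
        return field_output(self.u, self.beta)

    def step(self, h=None):
        """One Euler step of the field dynamics (in place)."""
        h_arr = 0.0 if h is None else np.asarray(h, dtype=float)
        with np.errstate(invalid="ignore"):
            drive = self.J @ np.tanh(self.beta * self.u) / self.n_s
            self.u = self.u + self.dt * (-self.u + drive - self.h_b + h_arr)
        if not np.all(np.isfinite(self.u)):
            raise FloatingPointError("neural-field potentials diverged")
        return self

    def velocity(self, centers, v0: float) -> np.ndarray:
        """Rectified population-vector readout of the goal vector."""
        w = np.maximum(0.0, self.output())
        c = np.asarray(centers)
        return (v0 / self.n_s) * np.array([w @ np.cos(c), w @ np.sin(c)])

    def heading_readout(self, centers, fallback=None):
        """Heading of the rectified population vector, in [0, 2*pi).

        When no neuron is positively active (or the active ones cancel
        exactly) the heading is undefined; ``fallback`` (the previous
        heading) is returned in that case.
        """
        w = np.maximum(0.0, self.output())
        c = np.asarray(centers)
        c_x = w @ np.cos(c)
        c_y = w @ np.sin(c)
        if c_x == 0.0 and c_y == 0.0:
            return fallback
        return float(wrap_angle(np.arctan2(c_y, c_x)))

    def roll(self, shift: int):
        """Circularly shift the potentials (frame re-anchoring)."""
        self.u = np.roll(self.u, shift)
        return self
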