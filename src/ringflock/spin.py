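"""Spin-system ring attractor.

``Ns`` binary neural groups (spins, sigma_i in {-1, +1}) sit on a ring at
preferred angles alpha_i = 2*pi*(i-1)/Ns with modified-cosine circulant
connectivity

    J_ij = cos(pi * (circ_dist(alpha_i, alpha_j) / pi)**nu).

The network state evolves under single-spin stochastic dynamics governed by
the Hamiltonian

    H = -[ (1/Ns) * sum_{i != j} J_ij sigma_i sigma_j
           + sum_i (h_i - h_b) sigma_i ],

where ``h`` is the sensory field on the ring and ``h_b`` a uniform
inhibition.  Energy-lowering flips are accepted with certainty and
energy-raising flips with probability exp(-beta * dH); beta acts as an
inverse neural-noise parameter.  Above the ordering transition a persistent
bump of active spins forms whose circular mean encodes the goal direction;
the movement readout averages the unit vectors of the active spins.

The double sum in the Hamiltonian excludes the self-pair i = j: with
sigma_i^2 = 1 the self term is a state-independent constant that cannot
affect flip probabilities, and excluding it keeps the O(1) cached energy
difference exact.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .geometry import circ_dist, ring_angles, wrap_angle

__all__ = [
    "build_connectivity",
    "receptive_centers",
    "spin_sensory_field",
    "bump_states",
    "SpinRingNetwork",
]


def bump_states(n_s: int, first_active: int, n_active: int) -> np.ndarray:
    """Spin configuration with one contiguous bump of active spins.

    Active spins occupy indices ``first_active .. first_active+n_active-1``
    (mod ``n_s``).  For ``nu = 1`` the energetically stable bump spans half
    the ring (``n_active = n_s // 2``): the pair energy is
    ``-(1/Ns) * |sum_i sigma_i e^{i alpha_i}|^2`` up to a constant, which a
    half-ring of active spins maximizes in magnitude.
    """
    s = -np.ones(n_s, dtype=np.int8)
    idx = (first_active + np.arange(n_active)) % n_s
    s[idx] = 1
    return s


def build_connectivity(n_s: int, nu: float) -> np.ndarray:
    """Circulant modified-cosine connectivity matrix.

    nu = 1 recovers a plain cosine kernel (balanced excitation/inhibition);
    nu < 1 sharpens local excitation and broadens inhibition.  The angular
    separation is the circular distance in [0, pi], which preserves ring
    symmetry for any nu.
    """
    if n_s < 3:
        raise ValueError(f"need at least 3 neurons on the ring, got Ns={n_s}")
    if not nu > 0:
        raise ValueError(f"connectivity exponent nu must be positive, got {nu}")
    alpha = ring_angles(n_s)
    dist = circ_dist(alpha[:, None], alpha[None, :])
    return np.cos(np.pi * (dist / np.pi) ** nu)


def receptive_centers(frame_mode: str, origin: float, n_s: int) -> np.ndarray:
    """World angles of the receptive-field centers, ``origin + alpha_i``.

    In the egocentric frame the origin is the agent's current heading, so
    the centers rotate with the body; in the allocentric frame the origin is
    the (fixed-between-switches) world anchor, so they do not.
    """
    if frame_mode not in ("ego", "allo"):
        raise ValueError(f"unknown frame mode {frame_mode!r}")
    return wrap_angle(origin + ring_angles(n_s))


def spin_sensory_field(centers, sources, sigma: float) -> np.ndarray:
    """Normalized-Gaussian sensory field on the ring.

    Each source ``(bearing, amplitude)`` contributes
    ``amplitude / sqrt(2*pi*sigma^2) * exp(-circ_dist(center, bearing)^2 /
    (2*sigma^2))`` to every neuron; sources add.
    """
    if not sigma > 0:
        raise ValueError(f"receptive width sigma must be positive, got {sigma}")
    centers = np.asarray(centers, dtype=float)
    h = np.zeros_like(centers)
    pref = 1.0 / np.sqrt(2.0 * np.pi * sigma**2)
    for bearing, amplitude in sources:
        d = circ_dist(centers, bearing)
        h += amplitude * pref * np.exp(-(d**2) / (2.0 * sigma**2))
    return h


class SpinRingNetwork:
    """State container plus dynamics for one spin-ring attractor.

    Parameters
    ----------
    n_s : number of spins on the ring.
    beta : inverse temperature of the stochastic update rule (>= 0).
    nu : connectivity exponent.
    h_b : uniform inhibition subtracted from every sensory input.
    t0 : equilibration sweeps per timestep (t0 * n_s attempts).
    states : optional initial spins in {-1, +1}; defaults to all inactive.
    connectivity : optional precomputed J (shared across agents); if
        omitted it is built from ``(n_s, nu)``.

    The instance caches the local field ``m = J @ states`` and keeps it
    consistent across flips, giving O(1) energy differences.
    """

    def __init__(self, n_s, beta, nu=1.0, h_b=0.0, t0=10, states=None,
                 connectivity=None):
        if beta < 0:
            raise ValueError(f"beta must be non-negative, got {beta}")
        if t0 < 1:
            raise ValueError(f"equilibration sweep count t0 must be >= 1, got {t0}")
        self.n_s = int(n_s)
        self.beta = float(beta)
        self.nu = float(nu)
        self.h_b = float(h_b)
        self.t0 = int(t0)
        self.J = build_connectivity(self.n_s, self.nu) if connectivity is None \
            else np.asarray(connectivity, dtype=float)
        if states is None:
            states = -np.ones(self.n_s)
        states = np.asarray(states)
        if states.shape != (self.n_s,) or not np.all(np.abs(states) == 1):
            raise ValueError("states must be a length-Ns vector of +-1")
        self.states = states.astype(np.int8)
        self._refresh_cache()

    # -- energy ---------------------------------------------------------

    def _refresh_cache(self):
        self.m = self.J @ self.states.astype(float)

    def hamiltonian(self, h=None) -> float:
        """Full energy of the current state under sensory field ``h``."""
        s = self.states.astype(float)
        if h is None:
            h = 0.0
        pair = s @ self.J @ s - self.n_s  # subtract the Ns self-pairs (J_ii=1)
        return -(pair / self.n_s + float(np.sum((h - self.h_b) * s)))

    def flip_delta(self, i: int, h=None) -> float:
        """Energy change of flipping spin ``i``, from the cached local field.

        Equals ``hamiltonian(after) - hamiltonian(before)`` exactly.
        """
        s = float(self.states[i])
        h_i = 0.0 if h is None else float(np.asarray(h)[i])
        return 2.0 * s * ((2.0 / self.n_s) * (self.m[i] - s) + h_i - self.h_b)

    # -- dynamics -------------------------------------------------------

    def equilibrate(self, h, rng, n_attempts=None):
        """Run ``t0 * n_s`` single-spin update attempts (in place).

        Neuron choices and acceptance uniforms are drawn from ``rng``; the
        induced chain has the Boltzmann distribution exp(-beta*H) as its
        stationary law.  dH = 0 proposals are accepted with probability 1
        (the continuous limit of exp(-beta*dH)).
        """
        if n_attempts is None:
            n_attempts = self.t0 * self.n_s
        idx = rng.integers(0, self.n_s, size=n_attempts)
        u = rng.random(n_attempts)
        h_arr = np.zeros(self.n_s) if h is None else np.asarray(h, dtype=float)
        _kernels.metropolis_run(self.states, self.m, self.J, self.beta,
                                h_arr, self.h_b, idx, u)
        return self

    def velocity(self, centers, v0: float) -> np.ndarray:
        """Speed vector ``(v0/Ns) * sum over active spins of their unit
        center vectors``; active means sigma_i = +1."""
        active = self.states == 1
        c = np.asarray(centers)[active]
        return (v0 / self.n_s) * np.array([np.cos(c).sum(), np.sin(c).sum()])

    def roll(self, shift: int):
        """Circularly shift the state by ``shift`` indices (frame re-anchoring)."""
        self.states = np.roll(self.states, shift)
        self._refresh_cache()
        return self

    # -- diagnostics ----------------------------------------------------

    def state_histogram(self, h, rng, n_samples, burn_in_sweeps=1000, thin=None):
        """Empirical occupancy of all 2**Ns states along the chain.

        Records one sample every ``thin`` attempts (default: one per sweep)
        after a burn-in.  Intended for small Ns, where it can be compared
        against the exactly enumerated Boltzmann distribution.
        """
        if self.n_s > 20:
            raise ValueError("state histogram is exhaustive; use Ns <= 20")
        if thin is None:
            thin = self.n_s
        h_arr = np.zeros(self.n_s) if h is None else np.asarray(h, dtype=float)
        burn = burn_in_sweeps * self.n_s
        self.equilibrate(h_arr, rng, n_attempts=burn)
        counts = np.zeros(2**self.n_s, dtype=np.int64)
        n_attempts = n_samples * thin
        idx = rng.integers(0, self.n_s, size=n_attempts)
        u = rng.random(n_attempts)
        _kernels.state_histogram_run(self.states, self.m, self.J, self.beta,
                                     h_arr, self.h_b, idx, u, thin, counts)
        self._refresh_cache()
        return counts
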