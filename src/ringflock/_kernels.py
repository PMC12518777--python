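"""Numba-compiled Monte Carlo kernels for the spin-ring network.

The inner single-spin update loop is the hot path of every spin-model
simulation (T0*Ns attempts per agent per timestep), so it is JIT compiled.
All randomness is pre-drawn with numpy generators by the caller and passed
in as arrays; the kernels themselves are deterministic, which keeps
reproducibility entirely in the hands of the seeding layer.

Update rule (single attempt): pick neuron ``i`` (given), compute the energy
difference ``dH`` of flipping it from the cached local field
``m_i = (J sigma)_i``, and accept with probability 1 if ``dH <= 0`` else
``exp(-beta*dH)``.  The cached field is updated in O(Ns) on acceptance.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["metropolis_run", "metropolis_run_multi", "state_histogram_run"]


@njit(cache=True)
def _delta_h(s, m_i, h_i, h_b, n_s):
    # dH for flipping sigma_i: 2*sigma_i*[(2/Ns)(m_i - J_ii sigma_i) + h_i - h_b]
    return 2.0 * s * ((2.0 / n_s) * (m_i - s) + h_i - h_b)


@njit(cache=True)
def metropolis_run(states, m, J, beta, h, h_b, idx, u):
    """Run one chain in place: ``len(idx)`` attempts on a single network.

    states : int8[Ns] in {-1,+1}, modified in place
    m      : float64[Ns] cached local field J @ states, kept consistent
    idx, u : pre-drawn neuron indices and uniforms, one pair per attempt
    """
    n_s = states.shape[0]
    for t in range(idx.shape[0]):
        i = idx[t]
        s = states[i]
        d_h = _delta_h(s, m[i], h[i], h_b, n_s)
        if d_h <= 0.0 or u[t] < np.exp(-beta * d_h):
            states[i] = -s
            delta = -2.0 * s
            for j in range(n_s):
                m[j] += J[j, i] * delta


@njit(cache=True)
def metropolis_run_multi(states, m, J, beta, h, h_b, idx, u):
    """Independent chains for N agents sharing one connectivity matrix.

    states, m, h : (N, Ns); idx, u : (N, A) with A attempts per agent.
    Each agent's chain consumes only its own row of randomness, so the
    result is identical to N separate ``metropolis_run`` calls.
    """
    n_agents, n_s = states.shape
    for a in range(n_agents):
        for t in range(idx.shape[1]):
            i = idx[a, t]
            s = states[a, i]
            d_h = _delta_h(s, m[a, i], h[a, i], h_b, n_s)
            if d_h <= 0.0 or u[a, t] < np.exp(-beta * d_h):
                states[a, i] = -s
                delta = -2.0 * s
                for j in range(n_s):
                    m[a, j] += J[j, i] * delta


@njit(cache=True)
def state_histogram_run(states, m, J, beta, h, h_b, idx, u, thin, counts):
    """Sample the chain's state occupancy for diagnostics.

    After every ``thin`` attempts the current state is recorded into
    ``counts`` (length ``2**Ns``), encoding spin ``+1`` at position ``i``
    as bit ``i``.  Total samples = ``len(idx) // thin``.  Only sensible
    for small ``Ns`` (exhaustive state space).
    """
    n_s = states.shape[0]
    code = 0
    for i in range(n_s):
        if states[i] == 1:
            code |= 1 << i
    for t in range(idx.shape[0]):
        i = idx[t]
        s = states[i]
        d_h = _delta_h(s, m[i], h[i], h_b, n_s)
        if d_h <= 0.0 or u[t] < np.exp(-beta * d_h):
            states[i] = -s
            delta = -2.0 * s
            for j in range(n_s):
                m[j] += J[j, i] * delta
            code ^= 1 << i
        if (t + 1) % thin == 0:
            counts[code] += 1
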