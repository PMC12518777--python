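"""Order parameters and decision metrics for simulated trajectories.

Global order (GO) is the angular order parameter: the norm of the mean unit
velocity vector over the population (the polarization of Vicsek-type
models).  Local order (LO) is its topological counterpart: for each agent,
the polarization over the k+1 topologically nearest agents (including
itself, minimum-image distances), averaged over agents and normalized by
k+1 so its maximum is 1.  Zero-speed agents contribute a zero vector to
either sum.

The decision metrics quantify single-agent target seeking: the first
passage time to close proximity of a target, and the time-averaged
agent-target distance normalized by the arena size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import PeriodicSpace

__all__ = [
    "unit_velocities", "global_order", "local_order", "mean_pair_distance",
    "decision_time", "mean_target_distance",
    "global_order_series", "local_order_series", "mean_pair_distance_series",
    "metrics_frame",
]

DEFAULT_K = 5


def unit_velocities(velocities) -> np.ndarray:
    """Normalize velocity vectors to unit length; zero vectors stay zero."""
    v = np.asarray(velocities, dtype=float)
    speed = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(speed > 0.0, v / speed, 0.0)
    return u


def global_order(velocities) -> float:
    """Norm of the mean unit velocity vector, in [0, 1]."""
    u = unit_velocities(velocities)
    if u.ndim != 2 or u.shape[0] < 1:
        raise ValueError("need at least one velocity vector")
    return float(np.linalg.norm(u.mean(axis=0)))


def _knn_indices(positions, k, space):
    """Indices of the k+1 topologically nearest agents (including self) per
    agent; distance ties break toward the smaller agent index."""
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    disp = space.displacement(pos[:, None, :], pos[None, :, :])
    dist = np.linalg.norm(disp, axis=-1)
    # stable sort on distance => equal distances keep ascending index order
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, : k + 1]


def local_order(positions, velocities, k: int = DEFAULT_K,
                space: PeriodicSpace | None = None, L: float | None = None) -> float:
    """Normalized topological local order, in [0, 1]."""
    if space is None:
        if L is None:
            raise ValueError("local_order needs a PeriodicSpace or L")
        space = PeriodicSpace(L)
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n < k + 1:
        raise ValueError(
            f"local order with k={k} needs at least {k + 1} agents, got {n}")
    u = unit_velocities(velocities)
    neigh = _knn_indices(pos, k, space)
    sums = u[neigh].sum(axis=1)  # (N, 2)
    return float(np.mean(np.linalg.norm(sums, axis=-1)) / (k + 1))


def mean_pair_distance(positions, space: PeriodicSpace | None = None,
                       L: float | None = None) -> float:
    """Average minimum-image distance over all ordered pairs,
    ``sum_{i != j} d_ij / (N (N-1))``."""
    if space is None:
        if L is None:
            raise ValueError("mean_pair_distance needs a PeriodicSpace or L")
        space = PeriodicSpace(L)
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("mean pair distance needs at least 2 agents")
    disp = space.displacement(pos[:, None, :], pos[None, :, :])
    dist = np.linalg.norm(disp, axis=-1)
    return float(dist.sum() / (n * (n - 1)))


def decision_time(agent_positions, target_positions, space: PeriodicSpace,
                  threshold: float = 5.0, times=None):
    """First recorded time at which the agent is within ``threshold`` of the
    target.

    Returns ``(time, censored)``; ``censored`` is True when the threshold is
    never reached within the trajectory (``time`` is then the last recorded
    time).  ``times`` defaults to 0..T-1 row indices.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    apos = np.atleast_2d(np.asarray(agent_positions, dtype=float))
    tpos = np.atleast_2d(np.asarray(target_positions, dtype=float))
    tpos = np.broadcast_to(tpos, apos.shape)
    d = space.distance(apos, tpos)
    if times is None:
        times = np.arange(len(d))
    hits = np.nonzero(d <= threshold)[0]
    if hits.size == 0:
        return int(times[-1]), True
    return int(times[hits[0]]), False


def mean_target_distance(agent_positions, target_positions,
                         space: PeriodicSpace, L: float | None = None,
                         burn_in: int = 0) -> float:
    """Time-averaged agent-target distance after ``burn_in`` recorded steps,
    normalized by the arena side (reported as d/L)."""
    apos = np.atleast_2d(np.asarray(agent_positions, dtype=float))
    tpos = np.atleast_2d(np.asarray(target_positions, dtype=float))
    tpos = np.broadcast_to(tpos, apos.shape)
    if burn_in >= len(apos):
        raise ValueError("burn_in must be shorter than the trajectory")
    d = space.distance(apos[burn_in:], tpos[burn_in:])
    side = space.L if L is None else L
    return float(np.mean(d) / side)


# ---------------------------------------------------------------------------
# per-timestep series over a recorded trajectory

def global_order_series(record) -> np.ndarray:
    return np.array([global_order(v) for v in record.velocities])


def local_order_series(record, k: int = DEFAULT_K,
                       space: PeriodicSpace | None = None) -> np.ndarray:
    if space is None:
        space = PeriodicSpace(record.config.L)
    return np.array([local_order(p, v, k=k, space=space)
                     for p, v in zip(record.positions, record.velocities)])


def mean_pair_distance_series(record,
                              space: PeriodicSpace | None = None) -> np.ndarray:
    if space is None:
        space = PeriodicSpace(record.config.L)
    return np.array([mean_pair_distance(p, space=space)
                     for p in record.positions])


def metrics_frame(record, k: int = DEFAULT_K,
                  space: PeriodicSpace | None = None) -> pd.DataFrame:
    """Per-timestep ``t, GO, LO, mean_pair_dist`` table for a recorded run.

    LO and the pair distance require enough agents; columns degenerate to
    NaN when the population is too small for them.
    """
    if space is None and record.config is not None:
        space = PeriodicSpace(record.config.L)
    if space is None:
        raise ValueError("metrics_frame needs a space (or a record with config)")
    n = record.n_agents
    go = global_order_series(record)
    if n >= k + 1:
        lo = np.array([local_order(p, v, k=k, space=space)
                       for p, v in zip(record.positions, record.velocities)])
    else:
        lo = np.full_like(go, np.nan)
    if n >= 2:
        mpd = np.array([mean_pair_distance(p, space=space)
                        for p in record.positions])
    else:
        mpd = np.full_like(go, np.nan)
    return pd.DataFrame({"t": record.times, "GO": go, "LO": lo,
                         "mean_pair_dist": mpd})
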