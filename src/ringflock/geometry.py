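"""Periodic 2-D geometry and circular (angular) arithmetic.

All simulations take place on a flat square torus of side ``L`` with the
minimum-image convention for distances and bearings.  Angles are world
angles in radians, measured counterclockwise from the +x axis and kept in
the canonical range ``[0, 2*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "PeriodicSpace",
    "wrap_angle",
    "circ_dist",
    "ring_angles",
]


def wrap_angle(theta):
    """Canonicalize angles to ``[0, 2*pi)``.  Idempotent; works on arrays."""
    w = np.mod(theta, TWO_PI)
    # float mod of a tiny negative can land exactly on the period
    return np.where(w == TWO_PI, 0.0, w)


def circ_dist(theta1, theta2):
    """Circular distance between angles, in ``[0, pi]``.

    ``min(|d|, 2*pi - |d|)`` with ``d = theta1 - theta2``; symmetric, and
    zero exactly when the angles coincide modulo ``2*pi``.
    """
    d = np.abs(wrap_angle(np.asarray(theta1) - np.asarray(theta2)))
    return np.minimum(d, TWO_PI - d)


def ring_angles(n: int) -> np.ndarray:
    """Preferred angles ``alpha_i = 2*pi*(i-1)/n`` of ``n`` neurons on a ring
    (0-based: index ``i`` maps to ``2*pi*i/n``)."""
    return TWO_PI * np.arange(n) / n


@dataclass(frozen=True)
class PeriodicSpace:
    """Square 2-D world of side ``L`` with periodic boundaries.

    Positions are continuous reals wrapped to the half-open box ``[0, L)``
    per coordinate.  Minimum-image displacement components lie in
    ``(-L/2, L/2]`` (ties at exactly ``L/2`` resolve to ``+L/2``).
    """

    L: float

    def __post_init__(self):
        if not self.L > 0:
            raise ValueError(f"space side L must be positive, got {self.L}")

    def wrap(self, p):
        """Wrap point(s) into ``[0, L)^2``.  Total and idempotent."""
        w = np.mod(np.asarray(p, dtype=float), self.L)
        return np.where(w == self.L, 0.0, w)

    def displacement(self, a, b):
        """Shortest vector from ``a`` to ``b`` on the torus.

        Broadcasts over leading axes; the last axis holds x, y.  Each
        component lies in ``(-L/2, L/2]``.
        """
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        # mod into [-L/2, L/2); then push the -L/2 boundary to +L/2
        d = np.mod(d + self.L / 2.0, self.L) - self.L / 2.0
        return np.where(d == -self.L / 2.0, self.L / 2.0, d)

    def distance(self, a, b):
        """Minimum-image Euclidean distance (symmetric in ``a``, ``b``)."""
        return np.linalg.norm(self.displacement(a, b), axis=-1)

    def bearing(self, a, b):
        """World angle of the minimum-image displacement from ``a`` to ``b``.

        Raises ``ValueError`` for coincident points, where the bearing is
        degenerate; callers that can tolerate coincidence must skip the
        source themselves.
        """
        d = self.displacement(a, b)
        if np.any(np.all(np.asarray(d) == 0.0, axis=-1)):
            raise ValueError("bearing undefined for coincident points")
        return wrap_angle(np.arctan2(d[..., 1], d[..., 0]))

    def bearing_matrix(self, positions: np.ndarray):
        """Pairwise bearings and distances among ``N`` positions.

        Returns ``(bearings, distances)`` of shape ``(N, N)``;
        ``bearings[i, j]`` is the bearing of ``j`` seen from ``i``.  The
        diagonal (and any coincident pair) is flagged with a NaN bearing
        rather than raising, since the simulation skips such sources.
        """
        d = self.displacement(positions[:, None, :], positions[None, :, :])
        dist = np.linalg.norm(d, axis=-1)
        with np.errstate(invalid="ignore"):
            bear = wrap_angle(np.arctan2(d[..., 1], d[..., 0]))
        bear = np.where(dist == 0.0, np.nan, bear)
        return bear, dist
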