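"""Periodic geometry helpers: wrapping and the minimum-image convention."""

from __future__ import annotations

import numpy as np

from .params import InvalidGeometryError


def wrap_positions(positions: np.ndarray, L: float) -> np.ndarray:
    """Fold coordinates into the primary cell ``[0, L)^3``."""
    if L <= 0:
        raise InvalidGeometryError(f"box edge must be positive, got L={L}")
    w = np.mod(np.asarray(positions, dtype=float), L)
    # np.mod of a tiny negative can round up to exactly L
    return np.where(w >= L, 0.0, w)


def minimum_image_displacement(r1, r2, L: float) -> np.ndarray:
    """Displacement ``r1 - r2`` under the minimum-image convention.

    Each component of the result lies in ``[-L/2, L/2)``; its norm is the
    true periodic distance between the two points.  Works on single
    triples or on ``(n, 3)`` arrays broadcast against each other.
    """
    if L <= 0:
        raise InvalidGeometryError(f"box edge must be positive, got L={L}")
    d = np.asarray(r1, dtype=float) - np.asarray(r2, dtype=float)
    d -= L * np.round(d / L)
    # np.round maps +-L/2 to the even side; force components into [-L/2, L/2)
    d = np.where(d >= L / 2, d - L, d)
    d = np.where(d < -L / 2, d + L, d)
    return d


def minimum_image_distance(r1, r2, L: float) -> np.ndarray:
    """Periodic distance between two points (or arrays of points)."""
    d = minimum_image_displacement(r1, r2, L)
    return np.sqrt(np.sum(d * d, axis=-1))


def all_pairs_within(positions: np.ndarray, L: float, r_cut: float):
    """Brute-force O(N^2) periodic pair search.

    Reference oracle for the cell list: returns ``(i, j, distance)``
    tuples with ``i < j`` and minimum-image distance ``<= r_cut``.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    out = []
    for i in range(n):
        if i + 1 == n:
            break
        d = minimum_image_distance(positions[i + 1:], positions[i], L)
        for k in np.nonzero(d <= r_cut)[0]:
            out.append((i, i + 1 + int(k), float(d[k])))
    return out
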