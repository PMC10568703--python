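"""Cell-list neighbor search for periodic boxes.

The box is decomposed into a cubic grid of cells with edge at least the
query cutoff (by construction ``>= sigma * (1 + epsilon)`` for bond-range
queries); candidate pairs are drawn only from the 27 neighboring cells, and
distances use the minimum-image convention.  Results are exact: a pair
query returns precisely the pairs an all-pairs scan would.
"""

from __future__ import annotations

import numpy as np

from .geometry import minimum_image_distance


class CellList:
    """Uniform cell decomposition of a cubic periodic box.

    Parameters
    ----------
    positions : (N, 3) array
        Coordinates wrapped into ``[0, L)``.
    L : float
        Box edge.
    min_cell : float
        Minimum cell edge; queries with ``r_cut`` larger than the actual
        cell edge are rejected.
    """

    def __init__(self, positions: np.ndarray, L: float, min_cell: float = 1.1):
        positions = np.asarray(positions, dtype=float)
        self.positions = positions
        self.L = float(L)
        self.n_cells = max(1, int(np.floor(L / min_cell)))
        self.cell_edge = self.L / self.n_cells
        idx = np.floor(positions / self.cell_edge).astype(np.int64)
        idx = np.clip(idx, 0, self.n_cells - 1)
        self._flat = (idx[:, 0] * self.n_cells + idx[:, 1]) * self.n_cells + idx[:, 2]
        order = np.argsort(self._flat, kind="stable")
        self._sorted_ids = order
        self._starts = np.searchsorted(self._flat[order], np.arange(self.n_cells**3))
        self._ends = np.searchsorted(self._flat[order], np.arange(self.n_cells**3), side="right")

    def _cell_members(self, cx: int, cy: int, cz: int) -> np.ndarray:
        flat = (cx * self.n_cells + cy) * self.n_cells + cz
        return self._sorted_ids[self._starts[flat]:self._ends[flat]]

    def query_pairs(self, r_cut: float):
        """All pairs ``(i, j, distance)`` with ``i < j`` and periodic distance <= r_cut."""
        if r_cut > self.cell_edge + 1e-12:
            raise ValueError(
                f"r_cut={r_cut} exceeds cell edge {self.cell_edge}; rebuild with a larger min_cell"
            )
        nc = self.n_cells
        pairs = []
        if nc < 3:
            # too few cells for the 27-stencil to be non-redundant: brute force
            from .geometry import all_pairs_within

            return all_pairs_within(self.positions, self.L, r_cut)
        for cx in range(nc):
            for cy in range(nc):
                for cz in range(nc):
                    home = self._cell_members(cx, cy, cz)
                    if len(home) == 0:
                        continue
                    # within-cell pairs
                    for a in range(len(home)):
                        i = home[a]
                        d = minimum_image_distance(
                            self.positions[home[a + 1:]], self.positions[i], self.L
                        )
                        for k in np.nonzero(d <= r_cut)[0]:
                            j = home[a + 1 + int(k)]
                            pairs.append((min(i, j), max(i, j), float(d[k])))
                    # half-stencil of 13 neighbor cells avoids double counting
                    for dx, dy, dz in _HALF_STENCIL:
                        other = self._cell_members((cx + dx) % nc, (cy + dy) % nc, (cz + dz) % nc)
                        if len(other) == 0:
                            continue
                        for i in home:
                            d = minimum_image_distance(
                                self.positions[other], self.positions[i], self.L
                            )
                            for k in np.nonzero(d <= r_cut)[0]:
                                j = other[int(k)]
                                pairs.append((min(i, j), max(i, j), float(d[k])))
        return [(int(i), int(j), dist) for i, j, dist in pairs]


# lexicographic ">" on offset tuples keeps exactly 13 of the 26 neighbor
# offsets, one per unordered cell pair (valid for n_cells >= 3)
_HALF_STENCIL = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def query_pairs(positions: np.ndarray, L: float, r_cut: float):
    """One-shot pair query; builds a throwaway :class:`CellList`."""
    return CellList(positions, L, min_cell=max(r_cut, 1e-9)).query_pairs(r_cut)
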