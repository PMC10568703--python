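"""Snapshot-level cluster statistics.

Everything here works on plain snapshot data (positions, bond list,
species labels, box edge) and is deliberately independent of the engine's
internal bookkeeping, so engine invariants can be cross-checked against
these routines.

Clusters are the connected components of the irreversible bond graph;
because bonds only join like species, every cluster is single-species.
The mass-average aggregation number is

    m_w = sum_m m^2 N(m) / sum_m m N(m),

and cluster geometry (radius of gyration) is measured after unwrapping
the cluster across periodic boundaries along a spanning tree of bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import minimum_image_displacement


# ----------------------------------------------------------------- labels

@dataclass
class ClusterLabeling:
    """Connected-component labels of the bond graph."""

    labels: np.ndarray  # (N,) component id per particle
    n_clusters: int
    species: np.ndarray | None = None  # per-particle species, if known

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def cluster_species(self) -> np.ndarray:
        """Species of each cluster (clusters are single-species by construction)."""
        if self.species is None:
            raise ValueError("labeling carries no species information")
        out = np.empty(self.n_clusters, dtype=self.species.dtype)
        out[self.labels] = self.species
        return out


def label_clusters(n: int, bonds: np.ndarray, species: np.ndarray | None = None
                   ) -> ClusterLabeling:
    """Label connected components of the bond graph on ``n`` particles."""
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    if len(bonds):
        data = np.ones(len(bonds), dtype=np.int8)
        g = coo_matrix((data, (bonds[:, 0], bonds[:, 1])), shape=(n, n))
        n_comp, labels = connected_components(g, directed=False)
    else:
        n_comp, labels = n, np.arange(n)
    return ClusterLabeling(labels=labels.astype(np.int64), n_clusters=n_comp,
                           species=None if species is None else np.asarray(species))


# ----------------------------------------------------------------- unwrap

def unwrap_cluster(members: np.ndarray, bonds: np.ndarray,
                   positions: np.ndarray, L: float):
    """Continuous coordinates of one cluster across periodic boundaries.

    Walks a spanning tree of the cluster's bonds, placing every member at
    its minimum-image offset from its tree parent.  Returns
    ``(coords, consistent)``: for a cluster that wraps the box (a
    percolating cluster) some non-tree bond closes a cycle with a nonzero
    net image shift, the unwrap is geometrically inconsistent and
    ``consistent`` is False (coordinates are still returned).
    """
    members = np.asarray(members, dtype=np.int64)
    index = {int(p): k for k, p in enumerate(members)}
    m = len(members)
    adj: list[list[int]] = [[] for _ in range(m)]
    for i, j in np.asarray(bonds, dtype=np.int64).reshape(-1, 2):
        if int(i) in index and int(j) in index:
            a, b = index[int(i)], index[int(j)]
            adj[a].append(b)
            adj[b].append(a)
    coords = np.zeros((m, 3))
    seen = np.zeros(m, dtype=bool)
    coords[0] = positions[members[0]]
    seen[0] = True
    stack = [0]
    consistent = True
    while stack:
        a = stack.pop()
        for b in adj[a]:
            d = minimum_image_displacement(positions[members[b]],
                                           positions[members[a]], L)
            if not seen[b]:
                coords[b] = coords[a] + d
                seen[b] = True
                stack.append(b)
            else:
                # non-tree bond: cycle closure must be image-consistent
                if not np.allclose(coords[b] - coords[a], d, atol=1e-6):
                    consistent = False
    if not seen.all():
        raise ValueError("unwrap_cluster requires a connected cluster")
    return coords, consistent


def radius_of_gyration(coords: np.ndarray) -> float:
    """Rg with ``Rg^2 = <|r - r_com|^2>`` over the member coordinates."""
    coords = np.asarray(coords, dtype=float)
    com = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1))))


# ----------------------------------------------------------------- scalars

def mass_average_aggregation_number(masses) -> float:
    """``m_w = sum m^2 N(m) / sum m N(m)`` from a list of cluster masses."""
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        return np.nan
    return float((masses**2).sum() / masses.sum())


def mass_average_from_histogram(sizes: np.ndarray, counts: np.ndarray) -> float:
    """Same statistic computed from a size histogram ``N(m)``."""
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    denom = (sizes * counts).sum()
    if denom == 0:
        return np.nan
    return float((sizes**2 * counts).sum() / denom)


def size_histogram(masses) -> tuple[np.ndarray, np.ndarray]:
    """Unique cluster sizes and their counts ``N(m)``."""
    masses = np.asarray(masses, dtype=np.int64)
    if masses.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.unique(masses, return_counts=True)


def average_bonded_neighbors(n: int, bonds: np.ndarray,
                             species: np.ndarray | None = None,
                             which: int | None = None) -> float:
    """Mean bond-graph degree, optionally restricted to one species.

    Unbonded particles count with degree zero, so early-time values start
    near 0 and grow as aggregation proceeds.
    """
    deg = np.zeros(n, dtype=np.int64)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    for col in (0, 1):
        np.add.at(deg, bonds[:, col], 1)
    if which is None or species is None:
        return float(deg.mean()) if n else np.nan
    mask = np.asarray(species) == which
    if not mask.any():
        return np.nan
    return float(deg[mask].mean())


# ------------------------------------------------------------- per-snapshot

@dataclass
class ClusterStats:
    """Per-snapshot, per-species cluster statistics."""

    species: int
    masses: np.ndarray
    m_w: float
    z_c: float
    rg: np.ndarray  # per-cluster Rg; nan where the unwrap is inconsistent
    spanning: np.ndarray  # per-cluster flag: wrap-inconsistent (percolating)

    @property
    def histogram(self):
        return size_histogram(self.masses)


def snapshot_cluster_stats(snapshot, species: int) -> ClusterStats:
    """All cluster statistics of one species in a snapshot.

    ``snapshot`` needs attributes ``positions``, ``species``, ``bonds``, ``L``.
    """
    spc = np.asarray(snapshot.species)
    n = len(spc)
    labeling = label_clusters(n, snapshot.bonds, spc)
    sizes = labeling.cluster_sizes()
    cl_species = np.empty(labeling.n_clusters, dtype=spc.dtype)
    cl_species[labeling.labels] = spc
    which = np.nonzero(cl_species == species)[0]
    masses = sizes[which]
    rgs = np.empty(len(which))
    spanning = np.zeros(len(which), dtype=bool)
    for k, lab in enumerate(which):
        mem = labeling.members(lab)
        if len(mem) == 1:
            rgs[k] = 0.0
            continue
        coords, consistent = unwrap_cluster(mem, snapshot.bonds,
                                            snapshot.positions, snapshot.L)
        if consistent:
            rgs[k] = radius_of_gyration(coords)
        else:
            rgs[k] = np.nan
            spanning[k] = True
    z_c = average_bonded_neighbors(n, snapshot.bonds, spc, species)
    return ClusterStats(species=species, masses=masses,
                        m_w=mass_average_aggregation_number(masses),
                        z_c=z_c, rg=rgs, spanning=spanning)
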