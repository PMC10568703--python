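"""Cluster topology under periodic boundaries.

* Percolation: a cluster spans the box along axis k when some bond closes
  a cycle whose net periodic-image shift along k is nonzero — the cluster
  connects to its own periodic image, the standard wrap-closure criterion.
  A gel of a species is any cluster of that species spanning any axis.
* Chemical distance: the bond count of a shortest path between the two
  graph-farthest monomers of a cluster (a pseudo-diameter pair located by
  a double breadth-first sweep); all monomers off that path are dangling
  ends.  The mass-versus-l scaling exponent d_f/d_b separates lattice
  animals (about 1.47) from reaction-limited clusters (about 2).
* State classification over replicates: a system is a bigel when at least
  half the replicates have both species percolating, a one-component gel
  when at least half have only B percolating, and fluid/flocs otherwise
  (the bigel rule takes precedence on exact ties).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image_displacement

FLUID = "fluid/flocs"
ONE_COMPONENT_GEL = "one-component gel"
BIGEL = "bigel"


# ------------------------------------------------------------ percolation

def detect_percolation(members, bonds, positions, L: float) -> np.ndarray:
    """Per-axis spanning flags of one connected cluster.

    Breadth-first traversal assigns every member an integer image vector
    by accumulating minimum-image bond increments; a bond whose closure
    mismatches the assigned images by a nonzero integer shift along axis
    k marks the cluster as spanning axis k.
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
    spans = np.zeros(3, dtype=bool)
    coords[0] = positions[members[0]]
    seen[0] = True
    queue = deque([0])
    while queue:
        a = queue.popleft()
        for b in adj[a]:
            d = minimum_image_displacement(positions[members[b]],
                                           positions[members[a]], L)
            if not seen[b]:
                coords[b] = coords[a] + d
                seen[b] = True
                queue.append(b)
            else:
                shift = np.rint((coords[a] + d - coords[b]) / L).astype(int)
                spans |= shift != 0
    if not seen.all():
        raise ValueError("detect_percolation requires a connected cluster")
    return spans


def species_percolates(n: int, bonds, positions, species, which, L: float) -> bool:
    """True when any cluster of the species spans any axis."""
    from .analysis import label_clusters

    labeling = label_clusters(n, bonds, np.asarray(species))
    sizes = labeling.cluster_sizes()
    # geometric prefilter: a cluster of m members cannot span a distance L
    # with bonds no longer than ~1.1 sigma unless m > L / 1.1
    min_size = int(L / 1.1)
    for lab in range(labeling.n_clusters):
        mem = labeling.members(lab)
        if len(mem) == 0 or species[mem[0]] != which:
            continue
        if sizes[lab] <= min_size:
            continue
        if detect_percolation(mem, bonds, positions, L).any():
            return True
    return False


def fill_to_percolation(n: int, positions, species, bonds, L: float,
                        which: int, seed: int = 0):
    """Bond set of a species driven to just below its percolation threshold.

    Starting from an existing (non-spanning) bond set, every additional
    same-species pair of `which` within the bonding range is a candidate
    bond; candidates are added one at a time in seeded random order,
    maintaining cluster image vectors with a union-find, and the filling
    stops just before the first bond that would close a wrap-around
    cycle (a spanning cluster).  The returned (E', 2) array realizes
    "just before the percolation threshold" at single-bond resolution,
    which whole-sweep snapshots straddle.  Bonds of the other species
    are passed through untouched.
    """
    from .neighbors import query_pairs

    positions = np.asarray(positions)
    species = np.asarray(species)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    have = {(int(i), int(j)) for i, j in np.sort(bonds, axis=1)}
    cand = []
    for i, j, _ in query_pairs(positions, L, 1.1):
        if species[i] == which and species[j] == which and (i, j) not in have:
            cand.append((i, j))
    rng = np.random.Generator(np.random.PCG64(seed))
    rng.shuffle(cand)

    parent = np.arange(n)
    # image vector of each particle relative to its cluster root
    img = np.zeros((n, 3), dtype=np.int64)

    def find(i):
        path = []
        while parent[i] != i:
            path.append(i)
            i = parent[i]
        shift = np.zeros(3, dtype=np.int64)
        for p in reversed(path):
            shift += img[p]
            img[p] = shift.copy()
            parent[p] = i
        return i

    def join(i, j):
        """Union across bond (i, j); returns False if it would span."""
        d = positions[i] - positions[j]
        delta = np.rint(d / L).astype(np.int64)
        ri, rj = find(i), find(j)
        if ri == rj:
            mismatch = img[i] - img[j] + delta
            return not np.any(mismatch)
        # attach rj under ri so that images stay consistent
        parent[rj] = ri
        img[rj] = img[i] + delta - img[j]
        return True

    accepted = list(map(tuple, bonds))
    for i, j in np.sort(bonds, axis=1):
        ok = join(int(i), int(j))
        if not ok:
            raise ValueError("existing bond set already spans")
    for i, j in cand:
        d = positions[i] - positions[j]
        delta = np.rint(d / L).astype(np.int64)
        ri, rj = find(i), find(j)
        if ri == rj:
            mismatch = img[i] - img[j] + delta
            if np.any(mismatch):
                break  # this bond closes a wrap cycle: stop just before
            accepted.append((i, j))
        else:
            parent[rj] = ri
            img[rj] = img[i] + delta - img[j]
            accepted.append((i, j))
    return np.asarray(accepted, dtype=np.int64).reshape(-1, 2)


# --------------------------------------------------------------- backbone

@dataclass
class BackboneResult:
    """Chemical distance and backbone of one cluster."""

    chemical_distance: int  # bonds along the backbone path
    backbone: np.ndarray  # particle ids along the path, endpoint to endpoint
    endpoints: tuple[int, int]
    dangling: np.ndarray  # members not on the backbone


def _bfs_farthest(adj: dict[int, list[int]], start: int):
    """Farthest node from start (ties -> lowest id), with predecessors."""
    dist = {start: 0}
    pred: dict[int, int] = {}
    queue = deque([start])
    far, far_d = start, 0
    while queue:
        a = queue.popleft()
        for b in sorted(adj[a]):
            if b not in dist:
                dist[b] = dist[a] + 1
                pred[b] = a
                queue.append(b)
                if dist[b] > far_d or (dist[b] == far_d and b < far):
                    far, far_d = b, dist[b]
    return far, far_d, pred


def backbone_chemical_distance(members, bonds) -> BackboneResult:
    """Pseudo-diameter backbone of a connected cluster of size >= 2.

    Endpoints come from a double BFS sweep; the backbone is one shortest
    path between them with ties broken toward the lowest particle id at
    each hop (BFS explores sorted adjacency, so the recorded predecessor
    is the lowest-id one at minimum distance).
    """
    members = np.asarray(members, dtype=np.int64)
    if len(members) < 2:
        raise ValueError("chemical distance is undefined for single particles")
    mset = set(int(p) for p in members)
    adj: dict[int, list[int]] = {int(p): [] for p in members}
    for i, j in np.asarray(bonds, dtype=np.int64).reshape(-1, 2):
        i, j = int(i), int(j)
        if i in mset and j in mset:
            adj[i].append(j)
            adj[j].append(i)
    start = int(members.min())
    e1, _, _ = _bfs_farthest(adj, start)
    e2, l, pred = _bfs_farthest(adj, e1)
    path = [e2]
    while path[-1] != e1:
        path.append(pred[path[-1]])
    path = np.asarray(path[::-1], dtype=np.int64)
    on_path = set(int(p) for p in path)
    dangling = np.asarray(sorted(mset - on_path), dtype=np.int64)
    return BackboneResult(chemical_distance=int(l), backbone=path,
                          endpoints=(int(e1), int(e2)), dangling=dangling)


# ----------------------------------------------------------- state calls

@dataclass
class StateCall:
    """Ensemble verdict over replicate (perc_A, perc_B) flags."""

    verdict: str
    n_replicates: int
    n_bigel: int
    n_b_only: int
    replicates: list[tuple[bool, bool]]


def classify_state(replicates) -> StateCall:
    """Half-rule classification of replicate percolation outcomes.

    Bigel when >= half the replicates percolate in both species (checked
    first); one-component gel when >= half percolate in B but not A;
    otherwise fluid/flocs.
    """
    reps = [(bool(a), bool(b)) for a, b in replicates]
    if not reps:
        raise ValueError("classify_state needs at least one replicate")
    n = len(reps)
    n_bigel = sum(1 for a, b in reps if a and b)
    n_b_only = sum(1 for a, b in reps if b and not a)
    if 2 * n_bigel >= n:
        verdict = BIGEL
    elif 2 * n_b_only >= n:
        verdict = ONE_COMPONENT_GEL
    else:
        verdict = FLUID
    return StateCall(verdict=verdict, n_replicates=n, n_bigel=n_bigel,
                     n_b_only=n_b_only, replicates=reps)
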