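"""Ground-truth fixture generators for the analysis toolchain.

Every analysis operation (cluster labeling, Rg, chemical distance,
percolation detection, exponent fits) has a deterministic or statistical
fixture here whose expected values are known from the construction, so
the analysis code can be tested without running any simulation.
Generation is pure: the same spec and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import radius_of_gyration
from .particles import ParticleSet


class FixtureError(ValueError):
    """Raised for geometrically infeasible fixture requests."""


@dataclass
class Fixture:
    """A bonded cluster (or gas) with expected-value metadata attached."""

    particles: ParticleSet
    bonds: np.ndarray  # (E, 2) int64
    expected: dict = field(default_factory=dict)


def _as_particles(coords: np.ndarray, L: float) -> ParticleSet:
    coords = np.mod(np.asarray(coords, dtype=float), L)
    return ParticleSet(coords, np.zeros(len(coords), dtype=np.int8), L)


def chain(n: int, spacing: float = 1.05, L: float | None = None) -> Fixture:
    """A straight bonded chain of n particles along x.

    Closed forms: ``Z_c = 2(n-1)/n``, chemical distance ``l = n-1``,
    ``Rg^2 = spacing^2 (n^2 - 1) / 12``; spans nothing.
    """
    if L is None:
        L = max(10.0, n * spacing + 2.0)
    if n * spacing >= L:
        raise FixtureError(f"chain of {n} at spacing {spacing} exceeds box {L}")
    coords = np.zeros((n, 3))
    coords[:, 0] = 0.5 + spacing * np.arange(n)
    coords[:, 1] = coords[:, 2] = L / 2
    bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    rg = spacing * np.sqrt((n * n - 1) / 12.0)
    return Fixture(_as_particles(coords, L), bonds, expected={
        "z_c": 2.0 * (n - 1) / n, "l": n - 1, "rg": rg,
        "spans": [False, False, False], "mass": n})


def spanning_chain(L: float) -> Fixture:
    """A bonded chain wrapping the box along x: percolates on x only.

    Needs an integer particle count n with ``1 < L/n <= 1.1``; raises
    :class:`FixtureError` when no such n exists (e.g. integer L = 10).
    """
    n = int(np.ceil(L / 1.1))
    spacing = L / n
    if not (1.0 < spacing <= 1.1):
        raise FixtureError(
            f"no chain spacing in (1, 1.1] wraps a box of L={L}; try L={n * 1.05:.2f}")
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    coords[:, 1] = coords[:, 2] = L / 2
    bonds = np.stack([np.arange(n), (np.arange(n) + 1) % n], axis=1)
    bonds = np.sort(bonds, axis=1)
    return Fixture(_as_particles(coords, L), bonds, expected={
        "spans": [True, False, False], "mass": n, "z_c": 2.0})


def ring(n: int, spacing: float = 1.05, L: float | None = None) -> Fixture:
    """A closed ring fitting inside the box: cycles but no spanning axis."""
    if n < 3:
        raise FixtureError("a ring needs at least 3 particles")
    radius = spacing / (2.0 * np.sin(np.pi / n))
    if L is None:
        L = 2 * radius + 4.0
    if 2 * radius + 1.0 >= L:
        raise FixtureError(f"ring of {n} particles does not fit in box {L}")
    theta = 2 * np.pi * np.arange(n) / n
    coords = np.stack([L / 2 + radius * np.cos(theta),
                       L / 2 + radius * np.sin(theta),
                       np.full(n, L / 2)], axis=1)
    bonds = np.stack([np.arange(n), (np.arange(n) + 1) % n], axis=1)
    bonds = np.sort(bonds, axis=1)
    return Fixture(_as_particles(coords, L), bonds, expected={
        "spans": [False, False, False], "mass": n, "z_c": 2.0,
        "l": n // 2})


_ARM_DIRECTIONS = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                            [-1, 0, 0], [0, -1, 0], [0, 0, -1]], dtype=float)


def star(arms: tuple[int, ...], spacing: float = 1.05,
         L: float | None = None) -> Fixture:
    """A hub with straight arms along coordinate axes.

    Chemical distance is the sum of the two longest arms; every particle
    off that path is a dangling end.
    """
    if not (1 <= len(arms) <= 6):
        raise FixtureError("star supports 1..6 arms")
    longest = max(arms)
    if L is None:
        L = 2 * longest * spacing + 4.0
    if 2 * longest * spacing + 1.0 >= L:
        raise FixtureError("star arms do not fit in the box")
    coords = [np.array([L / 2, L / 2, L / 2])]
    bonds = []
    for a, n_bonds in enumerate(arms):
        prev = 0
        for k in range(1, n_bonds + 1):
            coords.append(coords[0] + _ARM_DIRECTIONS[a] * spacing * k)
            bonds.append((prev, len(coords) - 1))
            prev = len(coords) - 1
    coords = np.asarray(coords)
    bonds = np.asarray(sorted(tuple(sorted(b)) for b in bonds), dtype=np.int64)
    two_longest = sorted(arms, reverse=True)[:2]
    l = sum(two_longest) if len(two_longest) == 2 else two_longest[0]
    n_dangling = sum(arms) - l
    return Fixture(_as_particles(coords, L), bonds, expected={
        "mass": len(coords), "l": l, "n_dangling": n_dangling,
        "spans": [False, False, False]})


def compact_blob(radius: float, spacing: float = 1.05,
                 L: float | None = None) -> Fixture:
    """A solid ball carved from a cubic lattice: a compact (d_f = 3) object."""
    if L is None:
        L = 2 * radius + 4.0
    k = int(np.ceil(radius / spacing))
    grid = np.arange(-k, k + 1) * spacing
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    if len(pts) == 0:
        raise FixtureError("blob radius too small")
    coords = pts + L / 2
    # bond nearest lattice neighbors (distance == spacing)
    from .neighbors import query_pairs

    wrapped = np.mod(coords, L)
    pairs = query_pairs(wrapped, L, spacing * 1.01)
    bonds = np.asarray([(i, j) for i, j, _ in pairs], dtype=np.int64)
    return Fixture(_as_particles(coords, L), bonds, expected={
        "mass": len(coords), "spans": [False, False, False]})


def random_lattice_tree(n: int, seed: int, spacing: float = 1.05,
                        L: float | None = None) -> Fixture:
    """A random tree grown by attachment on a cubic lattice (no loops).

    Useful for backbone/chemical-distance tests: the bond graph is an
    explicit tree, so shortest paths are unique.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    if L is None:
        L = (2 * n + 4) * spacing
    occupied = {(0, 0, 0): 0}
    sites = [(0, 0, 0)]
    bonds = []
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while len(sites) < n:
        base = rng.integers(len(sites))
        step = steps[rng.integers(6)]
        cand = tuple(np.add(sites[base], step))
        if cand in occupied:
            continue
        occupied[cand] = len(sites)
        bonds.append((base, len(sites)))
        sites.append(cand)
    coords = np.asarray(sites, dtype=float) * spacing + L / 2
    bonds = np.asarray(bonds, dtype=np.int64)
    return Fixture(_as_particles(coords, L), bonds, expected={"mass": n})


def hard_sphere_gas(n: int, L: float, seed: int) -> Fixture:
    """A dilute random non-overlapping gas (no bonds)."""
    from .engine import _kernels as _k

    state = _k.seed_rng(seed)
    pos, ok = _k.rsa_pack(n, L, 1.0, state, 5000)
    if not ok:
        raise FixtureError(f"could not pack {n} spheres in box {L}")
    return Fixture(_as_particles(pos, L), np.empty((0, 2), dtype=np.int64),
                   expected={"mass": 1})


# --------------------------------------------------------- statistical

def sample_power_law_masses(tau: float, m_cutoff: float, n: int,
                            seed: int) -> np.ndarray:
    """I.i.d. cluster masses from ``P(m) ~ m^-tau exp(-m/m_cutoff)``, m >= 1.

    Exact inverse-CDF sampling on the discrete distribution (truncated
    where the tail weight is negligible).
    """
    if tau <= 1:
        raise ValueError("tau must exceed 1")
    if m_cutoff <= 0:
        raise ValueError("m_cutoff must be positive")
    m_max = max(10, int(50 * m_cutoff))
    m = np.arange(1, m_max + 1, dtype=float)
    w = m ** (-tau) * np.exp(-m / m_cutoff)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    rng = np.random.Generator(np.random.PCG64(seed))
    u = rng.random(n)
    return (np.searchsorted(cdf, u) + 1).astype(np.int64)


def make_fractal_ensemble(target_df: float, sizes, seed: int = 0):
    """(mass, Rg) pairs with a known mass-radius exponent.

    ``target_df = 1``: explicit straight chains.  ``target_df = 3``:
    explicit compact balls.  Other values: hierarchical pair doubling --
    clusters merge pairwise at centre separation ``c * Rg`` chosen so
    that ``Rg`` scales as ``m**(1/target_df)`` exactly; the returned
    pairs follow the recursion, the ground truth of the construction.
    """
    sizes = list(sizes)
    if target_df == 1:
        masses, rgs = [], []
        for n in sizes:
            f = chain(int(n))
            masses.append(n)
            rgs.append(f.expected["rg"])
        return np.asarray(masses, float), np.asarray(rgs, float)
    if target_df == 3:
        masses, rgs = [], []
        for r in sizes:
            f = compact_blob(float(r))
            coords = f.particles.positions
            masses.append(f.expected["mass"])
            rgs.append(radius_of_gyration(coords))
        return np.asarray(masses, float), np.asarray(rgs, float)
    # hierarchical doubling: m_k = m0 * 2^k, Rg_k = Rg0 * 2^(k/1/df)
    n_gen = max(int(s) for s in sizes)
    m = 1.0
    rg = 0.5
    masses = [m]
    rgs = [rg]
    growth = 2.0 ** (1.0 / target_df)
    for _ in range(n_gen):
        m *= 2.0
        rg *= growth
        masses.append(m)
        rgs.append(rg)
    return np.asarray(masses), np.asarray(rgs)
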