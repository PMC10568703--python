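"""Particle containers and initial-configuration generation.

The starting state of every run is a well-mixed random packing of
``N_tot`` non-overlapping hard spheres, with species labels A/B assigned
at random in the ratio ``c_A : 1 - c_A``.  Random sequential insertion
is used up to ``phi_tot = 0.35``; denser systems start from a simple
cubic lattice whose species are randomized and which is then melted with
hard-sphere-only moves (attraction off) before t = 0, since random
insertion saturates near ``phi ~ 0.38``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image_distance
from .params import BoxSpec, ModelParams
from .engine import _kernels as _k

SPECIES_A = 0
SPECIES_B = 1
SPECIES_SYMBOLS = ("A", "B")

RSA_PHI_MAX = 0.35
PHI_MAX = 0.45
MELT_SWEEPS = 50


class PackingInfeasibleError(RuntimeError):
    """Raised when no valid hard-sphere packing could be constructed."""


@dataclass
class ParticleSet:
    """Instantaneous configuration: wrapped positions plus species labels."""

    positions: np.ndarray  # (N, 3), wrapped into [0, L)
    species: np.ndarray  # (N,) int8, 0 = A, 1 = B
    L: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.species) != len(self.positions):
            raise ValueError("species and positions lengths differ")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def n_a(self) -> int:
        return int(np.sum(self.species == SPECIES_A))

    @property
    def n_b(self) -> int:
        return int(np.sum(self.species == SPECIES_B))

    def species_symbols(self) -> list[str]:
        return [SPECIES_SYMBOLS[s] for s in self.species]

    def min_pair_distance(self) -> float:
        """Smallest minimum-image pair distance (O(N^2); for validation)."""
        n = self.n
        if n < 2:
            return np.inf
        best = np.inf
        for i in range(n - 1):
            d = minimum_image_distance(self.positions[i + 1:], self.positions[i], self.L)
            best = min(best, float(d.min()))
        return best


def assign_species(n_tot: int, c_A: float, rng: np.random.Generator) -> np.ndarray:
    """Random species labels with exactly ``round(c_A * n_tot)`` A particles."""
    n_a = round(c_A * n_tot)
    species = np.full(n_tot, SPECIES_B, dtype=np.int8)
    species[:n_a] = SPECIES_A
    rng.shuffle(species)
    return species


def _lattice_melt(n_tot: int, L: float, sigma: float, step: float,
                  seed: int, rng: np.random.Generator) -> np.ndarray:
    n_side = int(np.ceil(n_tot ** (1.0 / 3.0)))
    while n_side**3 < n_tot:
        n_side += 1
    spacing = L / n_side
    if spacing < sigma - 1e-12:
        raise PackingInfeasibleError(
            f"simple-cubic lattice of {n_tot} spheres does not fit in L={L}"
        )
    sites = rng.choice(n_side**3, size=n_tot, replace=False)
    iz = sites % n_side
    iy = (sites // n_side) % n_side
    ix = sites // (n_side * n_side)
    pos = (np.stack([ix, iy, iz], axis=1) + 0.5) * spacing
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    # melt with hard-sphere-only dynamics (no attraction, no clusters)
    from .engine.core import hard_sphere_equilibrate

    hard_sphere_equilibrate(pos, L, sigma, step, MELT_SWEEPS, seed)
    return pos


def build_initial_configuration(
    params: ModelParams, box: BoxSpec, seed: int | None = None
) -> ParticleSet:
    """Non-overlapping, well-mixed starting configuration.

    Raises :class:`PackingInfeasibleError` above ``phi_tot = 0.45`` or when
    both the insertion and lattice-melt routes fail.
    """
    phi = box.phi_tot
    if phi > PHI_MAX + 1e-12:
        raise PackingInfeasibleError(
            f"phi_tot={phi:.3f} exceeds the supported maximum {PHI_MAX}"
        )
    if seed is None:
        seed = params.seed
    rng = np.random.Generator(np.random.PCG64(seed))
    n = box.N_tot
    pos = None
    if phi <= RSA_PHI_MAX:
        kstate = _k.seed_rng(seed + 1)
        pos, ok = _k.rsa_pack(n, box.L, box.sigma, kstate, 5000)
        if not ok:
            pos = None
    if pos is None:
        pos = _lattice_melt(n, box.L, box.sigma, params.step_size, seed + 2, rng)
    species = assign_species(n, params.c_A, rng)
    return ParticleSet(positions=pos, species=species, L=box.L, sigma=box.sigma)
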