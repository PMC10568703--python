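"""The BCD propagator: state container, sweep driver and run orchestration.

The scheme per sweep:

1. ``N_tot`` trial moves on uniformly random particles.  A bonded particle
   of species X is granted the attempt with probability ``p_flex_X`` (the
   flexibility gate); an attempt displaces the particle by ``step_size``
   in a random direction and is rejected if it would overlap any particle
   (hard core) or stretch an existing bond beyond ``(1+epsilon)*sigma``.
   Accepted moves accumulate into the cluster's net Rouse displacement.
2. Every unbonded same-species pair within ``(1+epsilon)*sigma`` forms an
   irreversible bond.
3. Each non-spanning cluster of two or more particles attempts one rigid
   Zimm translation along its net Rouse direction (random for clusters
   that did not move internally, e.g. fully rigid ones).  The magnitude
   is ``s * sqrt(sigma / d_c)`` with ``d_c = 2*Rg + sigma``, so that the
   added centre-of-mass diffusion coefficient is ``D0 * sigma / d_c``.

Reduced time advances by ``step_size**2 / sigma**2`` per sweep: ``t0`` is
the time a free monomer needs to diffuse its own diameter (MSD = sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..params import BoxSpec, EngineParams, ModelParams
from ..particles import ParticleSet, SPECIES_A, SPECIES_B
from . import _kernels as _k


@dataclass
class Snapshot:
    """A retained configuration: positions, images, species and bonds."""

    sweep: int
    reduced_time: float
    positions: np.ndarray
    images: np.ndarray
    species: np.ndarray
    bonds: np.ndarray  # (E, 2) int32, i < j
    L: float
    sigma: float = 1.0

    @property
    def particles(self) -> ParticleSet:
        return ParticleSet(self.positions, self.species, self.L, self.sigma)


class SimulationState:
    """Mutable engine state: particle set + bond graph + RNG stream.

    Construct with :meth:`from_particles`; advance with :meth:`advance`.
    """

    def __init__(self, particles: ParticleSet, params: ModelParams):
        n = particles.n
        self.params = params
        self.L = float(particles.L)
        self.sigma = float(particles.sigma)
        self.n = n
        self.pos = particles.positions.copy()
        self.species = particles.species.copy()
        self.img = np.zeros((n, 3), dtype=np.int64)
        self.deg = np.zeros(n, dtype=np.int32)
        self.adj = np.full((n, _k.MAX_BONDS), -1, dtype=np.int32)
        self.parent = np.arange(n, dtype=np.int64)
        self.csize = np.ones(n, dtype=np.int64)
        self.head_m = np.arange(n, dtype=np.int64)
        self.next_m = np.full(n, -1, dtype=np.int64)
        self.tail_m = np.arange(n, dtype=np.int64)
        self.span = np.zeros((n, 3), dtype=np.bool_)
        self.rouse = np.zeros((n, 3), dtype=np.float64)
        self.move_credit = np.zeros(n, dtype=np.float64)
        self.moved = np.ones(n, dtype=np.uint8)
        self.spec_span = np.zeros(2, dtype=np.uint8)
        self.gel_sweep = np.full(2, -1, dtype=np.int64)
        self.sweep = 0
        self.rng = _k.seed_rng(params.seed)
        bond_range = params.bond_range
        self.ncell = max(1, int(np.floor(self.L / bond_range)))
        nc3 = self.ncell**3
        self.chead = np.full(nc3, -1, dtype=np.int64)
        self.cnext = np.full(n, -1, dtype=np.int64)
        self.cprev = np.full(n, -1, dtype=np.int64)
        self.ccell = np.zeros(n, dtype=np.int64)
        _k.build_cells(self.pos, self.L, self.ncell, self.chead, self.cnext,
                       self.cprev, self.ccell)
        self._p_flex = np.array([params.p_flex_A, params.p_flex_B])

    @classmethod
    def from_particles(cls, particles: ParticleSet, params: ModelParams,
                       bond_initial: bool = True) -> "SimulationState":
        state = cls(particles, params)
        if bond_initial:
            state.form_bonds()
        return state

    # ------------------------------------------------------------------
    @property
    def reduced_time(self) -> float:
        return self.sweep * self.params.step_size**2 / self.sigma**2

    def form_bonds(self) -> None:
        """Bond every unbonded same-species pair within the well range."""
        status = _k.initial_bond_pass(
            self.pos, self.img, self.species, self.deg, self.adj, self.parent,
            self.csize, self.head_m, self.next_m, self.tail_m, self.span,
            self.rouse, self.spec_span, self.gel_sweep, self.moved,
            self.chead, self.cnext, self.L, self.ncell, self.params.bond_range)
        if status != _k.OK:
            raise RuntimeError("bond adjacency overflow")

    def advance(self, n_sweeps: int, zimm: bool | None = None,
                bonding: bool = True, deterministic_gate: bool = False) -> None:
        """Run ``n_sweeps`` sweeps of the propagator."""
        if zimm is None:
            zimm = True
        status = _k.run_sweeps(
            self.pos, self.img, self.species, self.deg, self.adj, self.parent,
            self.csize, self.head_m, self.next_m, self.tail_m, self.span,
            self.rouse, self.move_credit, self.moved,
            self.chead, self.cnext, self.cprev,
            self.ccell, self.spec_span, self.gel_sweep, self.rng,
            self.L, self.ncell, self.sigma, self.params.bond_range,
            self.params.step_size, self._p_flex,
            zimm, deterministic_gate, bonding, n_sweeps, self.sweep)
        if status != _k.OK:
            raise RuntimeError("bond adjacency overflow")
        self.sweep += n_sweeps

    # ----------------------------------------------------------- measures
    def unwrapped_positions(self) -> np.ndarray:
        """Cluster-consistent continuous coordinates ``pos + img * L``."""
        return self.pos + self.img * self.L

    def bond_pairs(self) -> np.ndarray:
        """Edge list (E, 2) with i < j."""
        rows = []
        idx = np.nonzero(self.deg > 0)[0]
        for p in idx:
            nb = self.adj[p, : self.deg[p]]
            sel = nb > p
            if sel.any():
                rows.append(np.stack([np.full(sel.sum(), p, dtype=np.int32),
                                      nb[sel].astype(np.int32)], axis=1))
        if not rows:
            return np.empty((0, 2), dtype=np.int32)
        return np.concatenate(rows, axis=0)

    def cluster_roots(self) -> np.ndarray:
        return _k.roots_of(self.parent)

    def species_cluster_sizes(self, species: int) -> np.ndarray:
        """Sizes of the clusters of one species (singletons included)."""
        roots = self.cluster_roots()
        mask = self.species == species
        if not mask.any():
            return np.empty(0, dtype=np.int64)
        _, counts = np.unique(roots[mask], return_counts=True)
        return counts

    def mass_average_aggregation(self, species: int) -> float:
        sizes = self.species_cluster_sizes(species)
        if len(sizes) == 0:
            return np.nan
        return float((sizes.astype(float) ** 2).sum() / sizes.sum())

    def mean_bonded_neighbors(self, species: int) -> float:
        mask = self.species == species
        if not mask.any():
            return np.nan
        return float(self.deg[mask].mean())

    def largest_cluster_fraction(self, species: int) -> float:
        sizes = self.species_cluster_sizes(species)
        if len(sizes) == 0:
            return np.nan
        return float(sizes.max() / sizes.sum())

    def percolates(self, species: int) -> bool:
        return bool(self.spec_span[species])

    def gel_time(self, species: int) -> float:
        """First reduced time a spanning cluster of the species existed (nan if never)."""
        gs = self.gel_sweep[species]
        if gs < 0:
            return np.nan
        return float(gs) * self.params.step_size**2 / self.sigma**2

    def snapshot(self) -> Snapshot:
        return Snapshot(
            sweep=self.sweep, reduced_time=self.reduced_time,
            positions=self.pos.copy(), images=self.img.copy(),
            species=self.species.copy(), bonds=self.bond_pairs(),
            L=self.L, sigma=self.sigma)

    # ------------------------------------------------------------- restart
    def save(self, path) -> None:
        """Lossless restart file (npz)."""
        np.savez(path, pos=self.pos, img=self.img, species=self.species,
                 deg=self.deg, adj=self.adj, parent=self.parent,
                 csize=self.csize, head_m=self.head_m, next_m=self.next_m,
                 tail_m=self.tail_m, span=self.span,
                 move_credit=self.move_credit,
                 spec_span=self.spec_span, gel_sweep=self.gel_sweep,
                 sweep=np.int64(self.sweep), rng=self.rng,
                 L=self.L, sigma=self.sigma,
                 model=np.array(list(self.params.to_dict().items()), dtype=object))

    @classmethod
    def load(cls, path) -> "SimulationState":
        with np.load(path, allow_pickle=True) as f:
            model_kv = dict(f["model"])
            params = ModelParams(**{k: type(ModelParams.__dataclass_fields__[k].default)(v)
                                    for k, v in model_kv.items()})
            particles = ParticleSet(f["pos"], f["species"], float(f["L"]),
                                    float(f["sigma"]))
            state = cls(particles, params)
            for name in ("img", "deg", "adj", "parent", "csize", "head_m",
                         "next_m", "tail_m", "span", "move_credit",
                         "spec_span", "gel_sweep"):
                getattr(state, name)[...] = f[name]
            state.sweep = int(f["sweep"])
            state.rng = f["rng"].copy()
        return state


def hard_sphere_equilibrate(pos: np.ndarray, L: float, sigma: float,
                            step: float, sweeps: int, seed: int) -> None:
    """In-place hard-sphere-only MC melt (no bonding, no Zimm moves)."""
    particles = ParticleSet(pos, np.zeros(len(pos), dtype=np.int8), L, sigma)
    params = ModelParams(sigma=sigma, step_size=step, seed=seed, c_A=1.0)
    state = SimulationState(particles, params)  # no initial bonding
    state.advance(sweeps, zimm=False, bonding=False)
    pos[...] = state.pos


@dataclass
class RunResult:
    """Output of :func:`run_simulation`.

    ``kinetics`` has one row per checkpoint with columns ``sweep``,
    ``t_reduced``, ``m_w_A/B``, ``Zc_A/B``, ``fmax_A/B``, ``perc_A/B``.
    """

    kinetics: pd.DataFrame
    snapshots: list[Snapshot]
    state: SimulationState
    gel_time_A: float
    gel_time_B: float
    truncated: bool = False

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1] if self.snapshots else self.state.snapshot()


def _checkpoint_schedule(max_sweeps: int, factor: float):
    s = 1
    while s <= max_sweeps:
        yield s
        s = max(s + 1, int(np.ceil(s * factor)))


def run_simulation(
    params: ModelParams,
    box: BoxSpec,
    engine: EngineParams | None = None,
    particles: ParticleSet | None = None,
) -> RunResult:
    """Build an initial configuration and evolve it until a stop condition.

    Stop conditions (checked at geometric checkpoints): reaching
    ``max_reduced_time`` or ``max_sweeps``; percolation of every species
    present (if ``stop_on_percolation``); stationarity of ``m_w`` for every
    species (if ``stop_when_stationary``): relative change below
    ``stationary_rtol`` over the trailing decade of reduced time.
    """
    from ..particles import build_initial_configuration

    if engine is None:
        engine = EngineParams()
    if particles is None:
        particles = build_initial_configuration(params, box)
    state = SimulationState.from_particles(particles, params)

    dt = params.step_size**2 / state.sigma**2
    max_sweeps = min(engine.max_sweeps, int(np.ceil(engine.max_reduced_time / dt)))
    rows = []
    snapshots: list[Snapshot] = []
    has_A = particles.n_a > 0
    has_B = particles.n_b > 0

    def record(k_index: int):
        row = {
            "sweep": state.sweep,
            "t_reduced": state.reduced_time,
            "m_w_A": state.mass_average_aggregation(SPECIES_A) if has_A else np.nan,
            "m_w_B": state.mass_average_aggregation(SPECIES_B) if has_B else np.nan,
            "Zc_A": state.mean_bonded_neighbors(SPECIES_A) if has_A else np.nan,
            "Zc_B": state.mean_bonded_neighbors(SPECIES_B) if has_B else np.nan,
            "fmax_A": state.largest_cluster_fraction(SPECIES_A) if has_A else np.nan,
            "fmax_B": state.largest_cluster_fraction(SPECIES_B) if has_B else np.nan,
            "perc_A": state.percolates(SPECIES_A),
            "perc_B": state.percolates(SPECIES_B),
        }
        rows.append(row)
        if engine.keep_snapshots and k_index % engine.snapshot_every == 0:
            snapshots.append(state.snapshot())
        return row

    record(0)
    stop_requested = engine.stop_on_percolation or engine.stop_when_stationary
    stopped_early = False
    k_index = 0
    for target in _checkpoint_schedule(max_sweeps, engine.checkpoint_factor):
        state.advance(target - state.sweep, zimm=engine.zimm_enabled,
                      deterministic_gate=engine.deterministic_gate)
        k_index += 1
        row = record(k_index)
        if engine.stop_on_percolation:
            done = (not has_A or row["perc_A"]) and (not has_B or row["perc_B"])
            if done:
                stopped_early = True
                break
        if engine.stop_when_stationary and row["t_reduced"] >= 10 * dt:
            t_now = row["t_reduced"]
            past = [r for r in rows if r["t_reduced"] <= t_now / 10.0]
            if past:
                ref = past[-1]
                ok = True
                for sp, col in ((has_A, "m_w_A"), (has_B, "m_w_B")):
                    if sp and abs(row[col] - ref[col]) > engine.stationary_rtol * row[col]:
                        ok = False
                if ok:
                    stopped_early = True
                    break
    # a run is flagged truncated when a stop condition was requested but
    # never reached within the sweep/time budget
    truncated = stop_requested and not stopped_early

    kinetics = pd.DataFrame(rows)
    return RunResult(
        kinetics=kinetics, snapshots=snapshots, state=state,
        gel_time_A=state.gel_time(SPECIES_A), gel_time_B=state.gel_time(SPECIES_B),
        truncated=truncated)
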