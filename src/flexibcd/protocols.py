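"""Scaled-down study protocols.

The headline results (exponents d_f, tau, d_f/d_b, Z_c plateaus, growth
kinetics, critical parameters) are defined at a production scale of
L = 50 with ~1e5 particles; the protocols here reproduce them at desk
scale (L = 20, ~4.6e3 particles at phi_tot = 0.3), the conditions under
which this package's results are quoted.  Each protocol runs the
simulator from scratch and measures its observable with the analysis
toolchain; nothing is read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import label_clusters, snapshot_cluster_stats
from .engine.core import RunResult, Snapshot, run_simulation
from .params import BoxSpec, EngineParams, ModelParams
from .particles import SPECIES_A, SPECIES_B
from .powerlaw import (PowerLawFit, fit_backbone_scaling,
                       fit_fractal_dimension, fit_size_distribution_exponent)
from .topology import backbone_chemical_distance, fill_to_percolation

# study conditions for the exponent analyses
EXPONENT_PHI = 0.3
EXPONENT_CA = 0.2
EXPONENT_L = 20.0
EXPONENT_PFLEX = (0.1, 0.5, 1.0)
FLOC_MW_WINDOW = (3.0, 20.0)  # flocculation window in m_w for the tau pool

# study conditions for the bonded-neighbor plateaus
ZC_PHI = 0.3
ZC_CA = 0.4
ZC_L = 20.0

# study conditions for the growth-kinetics check
GROWTH_PHI = 0.04
GROWTH_L = 24.0


@dataclass
class ExponentStudy:
    """Pooled cluster pools and exponent fits from the scaled-down runs."""

    d_f_A: PowerLawFit
    tau_A: PowerLawFit
    backbone_A: PowerLawFit
    d_f_B: PowerLawFit
    tau_B: PowerLawFit
    runs: list[RunResult] = field(repr=False, default_factory=list)
    pooled_A: dict = field(repr=False, default_factory=dict)
    pooled_B: dict = field(repr=False, default_factory=dict)


def _last_presperc_snapshot(params: ModelParams, box: BoxSpec, species: int,
                            max_sweeps: int = 5000):
    """Replay a run at one-sweep resolution; return the last snapshot
    before the species forms a spanning cluster."""
    from .engine.core import SimulationState
    from .particles import build_initial_configuration

    particles = build_initial_configuration(params, box)
    state = SimulationState.from_particles(particles, params)
    prev = state.snapshot()
    while not state.percolates(species) and state.sweep < max_sweeps:
        prev = state.snapshot()
        state.advance(1)
    return prev


def _species_backbones(snapshot, species: int, min_mass: int = 2):
    """(mass, chemical distance) for every cluster of a species."""
    lab = label_clusters(len(snapshot.species), snapshot.bonds, snapshot.species)
    sizes = lab.cluster_sizes()
    cl_sp = np.empty(lab.n_clusters, dtype=snapshot.species.dtype)
    cl_sp[lab.labels] = snapshot.species
    out = []
    for k in np.nonzero((cl_sp == species) & (sizes >= min_mass))[0]:
        res = backbone_chemical_distance(lab.members(k), snapshot.bonds)
        out.append((int(sizes[k]), res.chemical_distance))
    return out


def run_exponent_study(seed: int, max_reduced_time: float = 60.0,
                       p_flex_values=EXPONENT_PFLEX,
                       L: float = EXPONENT_L,
                       n_b_configs: int = 10) -> ExponentStudy:
    """The self-similarity analysis at phi_tot = 0.3, c_A = 0.2.

    One run per flexibility value.  A-species clusters are pooled across
    snapshots before A percolates (it stays finite below the critical
    concentration): all pre-percolation snapshots with m_w >= the
    flocculation onset feed the d_f and backbone fits, and the
    flocculation window (m_w in [3, 20]) feeds the tau fit.  B-species
    clusters come from configurations driven to just below the B
    percolation threshold, pooled over ``n_b_configs`` replicates.
    """
    box = BoxSpec.from_phi(EXPONENT_PHI, L)
    runs = []
    A_m, A_rg, A_ml = [], [], []
    A_m_floc = []
    B_m, B_rg = [], []
    for k, p_flex in enumerate(p_flex_values):
        params = ModelParams(c_A=EXPONENT_CA, p_flex_A=p_flex,
                             seed=seed + 1000 * k)
        engine = EngineParams(max_reduced_time=max_reduced_time,
                              checkpoint_factor=1.25)
        result = run_simulation(params, box, engine)
        runs.append(result)
        kin = result.kinetics

        # ---- A pools -------------------------------------------------
        for snap, (_, row) in zip(result.snapshots, kin.iterrows()):
            if row.perc_A:
                break
            if row.m_w_A < 3.0:
                continue  # pre-flocculation: mostly monomers/dimers
            stats = snapshot_cluster_stats(snap, SPECIES_A)
            keep = ~stats.spanning
            A_m.extend(stats.masses[keep])
            A_rg.extend(stats.rg[keep])
            A_ml.extend(_species_backbones(snap, SPECIES_A))
            if FLOC_MW_WINDOW[0] <= row.m_w_A <= FLOC_MW_WINDOW[1]:
                A_m_floc.extend(stats.masses[keep])

    # ---- B pool: just below the B percolation threshold --------------
    # B gels within a few sweeps at these densities, so near-threshold
    # configurations are cheap: a sweep-resolution replay finds the last
    # pre-spanning state, and the candidate bonds of the gelling sweep
    # are then added one at a time up to (not including) the first
    # wrap-closing bond, placing the analyzed configuration at the
    # threshold itself.  Ten replicate configurations are pooled (the
    # first ones coincide with the runs above); the near-threshold B
    # structure does not depend on the A flexibility.
    for k in range(n_b_configs):
        p_flex = p_flex_values[k] if k < len(p_flex_values) else 1.0
        params_b = ModelParams(c_A=EXPONENT_CA, p_flex_A=p_flex,
                               seed=seed + 1000 * k)
        snap_b = _last_presperc_snapshot(params_b, box, SPECIES_B)
        bonds_crit = fill_to_percolation(
            len(snap_b.species), snap_b.positions, snap_b.species,
            snap_b.bonds, snap_b.L, SPECIES_B, seed=seed + 1000 * k)
        crit = Snapshot(sweep=snap_b.sweep, reduced_time=snap_b.reduced_time,
                        positions=snap_b.positions, images=snap_b.images,
                        species=snap_b.species, bonds=bonds_crit, L=snap_b.L)
        stats_b = snapshot_cluster_stats(crit, SPECIES_B)
        keep = ~stats_b.spanning
        B_m.extend(stats_b.masses[keep])
        B_rg.extend(stats_b.rg[keep])

    A_m = np.asarray(A_m, dtype=float)
    A_rg = np.asarray(A_rg, dtype=float)
    A_ml = np.asarray(A_ml, dtype=float).reshape(-1, 2)
    B_m = np.asarray(B_m, dtype=float)
    B_rg = np.asarray(B_rg, dtype=float)
    # backbone fit over the branched regime: below l ~ 5 bonds clusters
    # are trivially chain-like (m ~ l + 1, slope -> 1) and mask the
    # lattice-animal scaling
    sel = A_ml[:, 1] >= 5
    return ExponentStudy(
        d_f_A=fit_fractal_dimension(A_m, A_rg),
        tau_A=fit_size_distribution_exponent(np.asarray(A_m_floc, dtype=float)),
        backbone_A=fit_backbone_scaling(A_ml[sel, 0], A_ml[sel, 1]),
        d_f_B=fit_fractal_dimension(B_m, B_rg),
        tau_B=fit_size_distribution_exponent(B_m),
        runs=runs,
        pooled_A={"m": A_m, "rg": A_rg, "ml": A_ml,
                  "m_floc": np.asarray(A_m_floc, dtype=float)},
        pooled_B={"m": B_m, "rg": B_rg},
    )


@dataclass
class PlateauStudy:
    """Late-time bonded-neighbor plateau of the A species."""

    z_c_plateau: float
    p_flex: float
    kinetics: object = field(repr=False, default=None)
    stationary: bool = True


def run_zc_plateau_study(p_flex: float, seed: int,
                         max_reduced_time: float = 250.0,
                         L: float = ZC_L) -> PlateauStudy:
    """Z_c(A) plateau at phi_tot = 0.3, c_A = 0.4.

    Runs until Z_c changes by less than 1% per decade of reduced time (or
    the time cap) and reports the mean over the trailing decade.
    """
    params = ModelParams(c_A=ZC_CA, p_flex_A=p_flex, seed=seed)
    box = BoxSpec.from_phi(ZC_PHI, L)
    engine = EngineParams(max_reduced_time=max_reduced_time,
                          checkpoint_factor=1.3, keep_snapshots=False)
    result = run_simulation(params, box, engine)
    kin = result.kinetics
    t_end = kin.t_reduced.iloc[-1]
    tail = kin[kin.t_reduced >= t_end / 10.0]
    ref = kin[kin.t_reduced <= t_end / 10.0]
    stationary = True
    if len(ref):
        z0 = ref.Zc_A.iloc[-1]
        z1 = kin.Zc_A.iloc[-1]
        stationary = bool(abs(z1 - z0) <= 0.01 * max(z1, 1e-9) * 1.0
                          or abs(z1 - z0) < 0.05)
    return PlateauStudy(z_c_plateau=float(tail.Zc_A.mean()), p_flex=p_flex,
                        kinetics=kin, stationary=stationary)


@dataclass
class GrowthStudy:
    """Flocculation-stage growth exponent of m_w vs reduced time."""

    exponent: float
    window: tuple[float, float]
    kinetics: object = field(repr=False, default=None)


def run_growth_study(seed: int, max_reduced_time: float = 60.0,
                     phi: float = GROWTH_PHI, L: float = GROWTH_L) -> GrowthStudy:
    """Dilute single-species aggregation: m_w grows ~linearly with t/t0.

    The growth exponent is the log-log slope of (m_w - 1) vs reduced time
    over the flocculation window m_w in [3, 30] (subtracting the monomer
    baseline removes the early-time offset), stopping before percolation.
    """
    params = ModelParams(c_A=1.0, seed=seed)
    box = BoxSpec.from_phi(phi, L)
    engine = EngineParams(max_reduced_time=max_reduced_time,
                          checkpoint_factor=1.3, keep_snapshots=False,
                          stop_on_percolation=True)
    result = run_simulation(params, box, engine)
    kin = result.kinetics
    sel = (kin.m_w_A >= 3.0) & (kin.m_w_A <= 30.0) & (~kin.perc_A)
    x = np.log10(kin.t_reduced[sel])
    y = np.log10(kin.m_w_A[sel] - 1.0)
    slope = float(np.polyfit(x, y, 1)[0]) if sel.sum() >= 3 else np.nan
    lo = float(kin.t_reduced[sel].min()) if sel.any() else np.nan
    hi = float(kin.t_reduced[sel].max()) if sel.any() else np.nan
    return GrowthStudy(exponent=slope, window=(lo, hi), kinetics=kin)


def run_early_collapse_study(seed: int, p_flex_values=EXPONENT_PFLEX,
                             t_early: float = 1e-2, L: float = EXPONENT_L):
    """Early-time m_w(A) at phi_tot = 0.3, c_A = 0.2 for several p_flex.

    Before bonded structure builds up (t/t0 < 1e-2) the growth curves at
    different flexibilities coincide; returns {p_flex: m_w_A(t_early)}.
    """
    box = BoxSpec.from_phi(EXPONENT_PHI, L)
    out = {}
    for k, p_flex in enumerate(p_flex_values):
        params = ModelParams(c_A=EXPONENT_CA, p_flex_A=p_flex,
                             seed=seed + 1000 * k)
        engine = EngineParams(max_reduced_time=t_early,
                              checkpoint_factor=1.5, keep_snapshots=False)
        result = run_simulation(params, box, engine)
        out[p_flex] = float(result.kinetics.m_w_A.iloc[-1])
    return out
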