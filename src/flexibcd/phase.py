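"""Ensemble orchestration: gel/bigel state diagrams and critical scans.

A phase point (phi_tot, c_A, p_flex_A) is classified from ``n_replicates``
independent initial configurations: each replicate runs until both
species have either percolated or stopped growing (or a reduced-time
cap), and the half-rule of :func:`flexibcd.topology.classify_state`
turns the replicate (perc_A, perc_B) flags into a verdict.  Critical
values are grid estimates: the smallest c_A (or p_flex) whose verdict is
bigel, with an uncertainty of one grid step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine.core import run_simulation
from .params import BoxSpec, EngineParams, ModelParams
from .topology import BIGEL, StateCall, classify_state

DEFAULT_L = 20.0
DEFAULT_REPLICATES = 10
DEFAULT_TIME_CAP = 100.0


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic replicate seed from a base seed and grid indices (< 2^31)."""
    mask = (1 << 64) - 1
    h = (int(base_seed) ^ 0x9E3779B97F4A7C15) & mask
    for ix in indices:
        h ^= (int(ix) + 0x9E3779B97F4A7C15 + (h << 6) + (h >> 2)) & mask
        h = (h * 0xBF58476D1CE4E5B9) & mask
        h ^= h >> 29
    return h % (2**31 - 1)


@dataclass
class PhasePoint:
    """Replicate-level classification of one (phi_tot, c_A, p_flex_A) point."""

    phi_tot: float
    c_A: float
    p_flex_A: float
    L: float
    call: StateCall
    seeds: list[int]
    mean_gel_time_A: float
    mean_gel_time_B: float
    failures: int = 0

    @property
    def verdict(self) -> str:
        return self.call.verdict


def evaluate_phase_point(
    phi_tot: float, c_A: float, p_flex_A: float,
    L: float = DEFAULT_L, n_replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0, indices: tuple[int, ...] = (),
    max_reduced_time: float = DEFAULT_TIME_CAP,
    step_size: float = 0.05,
    stop_when_stationary: bool = True,
) -> PhasePoint:
    """Classify one phase point from independent replicate runs.

    Each replicate stops once every present species has percolated, or
    (if ``stop_when_stationary``) once aggregation has stalled, or at
    the reduced-time cap.  Near a transition the stationarity stop can
    fire before slow gelation completes; disable it for runs that must
    exhaust the time budget.
    """
    box = BoxSpec.from_phi(phi_tot, L)
    flags = []
    seeds = []
    tg_a, tg_b = [], []
    failures = 0
    for rep in range(n_replicates):
        seed = derive_seed(base_seed, *indices, rep)
        seeds.append(seed)
        params = ModelParams(c_A=c_A, p_flex_A=p_flex_A, seed=seed,
                             step_size=step_size)
        engine = EngineParams(max_reduced_time=max_reduced_time,
                              stop_on_percolation=True,
                              stop_when_stationary=stop_when_stationary,
                              keep_snapshots=False)
        try:
            result = run_simulation(params, box, engine)
        except Exception:
            failures += 1
            continue
        state = result.state
        # degenerate compositions: an absent A species cannot form the
        # second network (flag False), while an absent B species makes the
        # majority-gel requirement vacuous (flag True), so a pure-A
        # gel-forming system classifies as bigel and a pure-B one as a
        # one-component gel
        n_a = int(np.sum(state.species == 0))
        n_b = state.n - n_a
        perc_a = state.percolates(0) if n_a else False
        perc_b = state.percolates(1) if n_b else True
        flags.append((perc_a, perc_b))
        if np.isfinite(result.gel_time_A):
            tg_a.append(result.gel_time_A)
        if np.isfinite(result.gel_time_B):
            tg_b.append(result.gel_time_B)
    if not flags:
        raise RuntimeError("all replicate runs failed at this phase point")
    call = classify_state(flags)
    return PhasePoint(
        phi_tot=phi_tot, c_A=c_A, p_flex_A=p_flex_A, L=L, call=call,
        seeds=seeds,
        mean_gel_time_A=float(np.mean(tg_a)) if tg_a else np.nan,
        mean_gel_time_B=float(np.mean(tg_b)) if tg_b else np.nan,
        failures=failures)


@dataclass
class CriticalScan:
    """Result of a 1D critical-parameter scan."""

    axis: str  # "c_A" or "p_flex"
    grid: np.ndarray
    points: list[PhasePoint]
    critical: float  # nan when no bigel appears anywhere on the grid
    grid_step: float
    open_ended: bool
    confirmed: bool  # all grid points above the estimate are bigel too
    L: float


def _scan_axis(axis: str, grid, make_point) -> CriticalScan:
    grid = np.asarray(sorted(grid), dtype=float)
    points = [make_point(k, v) for k, v in enumerate(grid)]
    verdicts = [p.verdict for p in points]
    critical = np.nan
    open_ended = True
    confirmed = False
    for k, v in enumerate(verdicts):
        if v == BIGEL:
            critical = float(grid[k])
            open_ended = False
            confirmed = all(w == BIGEL for w in verdicts[k:])
            break
    step = float(np.min(np.diff(grid))) if len(grid) > 1 else np.nan
    return CriticalScan(axis=axis, grid=grid, points=points, critical=critical,
                        grid_step=step, open_ended=open_ended,
                        confirmed=confirmed, L=points[0].L)


def scan_critical_concentration(
    phi_tot: float, p_flex_A: float, c_A_grid,
    n_replicates: int = DEFAULT_REPLICATES, L: float = DEFAULT_L,
    base_seed: int = 0, **kw) -> CriticalScan:
    """Smallest c_A on the grid whose verdict is bigel (+- one grid step)."""
    def make(k, c_A):
        return evaluate_phase_point(phi_tot, c_A, p_flex_A, L=L,
                                    n_replicates=n_replicates,
                                    base_seed=base_seed, indices=(0, k, 0), **kw)
    return _scan_axis("c_A", c_A_grid, make)


def scan_critical_flexibility(
    phi_tot: float, c_A: float, p_flex_grid,
    n_replicates: int = DEFAULT_REPLICATES, L: float = DEFAULT_L,
    base_seed: int = 0, **kw) -> CriticalScan:
    """Smallest p_flex on the grid whose verdict is bigel (+- one grid step)."""
    def make(k, p_flex):
        return evaluate_phase_point(phi_tot, c_A, p_flex, L=L,
                                    n_replicates=n_replicates,
                                    base_seed=base_seed, indices=(1, 0, k), **kw)
    return _scan_axis("p_flex", p_flex_grid, make)


@dataclass
class StateDiagram:
    """Grid of phase points with critical-value summaries."""

    points: list[PhasePoint]
    table: pd.DataFrame
    critical_flexibility: pd.DataFrame  # per (phi_tot, c_A): smallest bigel p_flex
    critical_concentration: pd.DataFrame  # per (phi_tot, p_flex): smallest bigel c_A
    monotonicity_violations: list[tuple]


def build_state_diagram(
    phi_grid, c_A_grid, p_flex_grid,
    L: float = DEFAULT_L, n_replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0, **kw) -> StateDiagram:
    """Classify every (phi_tot, c_A, p_flex) grid point.

    Replicate seeds derive deterministically from the base seed and the
    grid indices, so a rerun reproduces the table exactly.  Individual
    run failures are recorded per point and the scan continues.
    """
    phi_grid = np.asarray(sorted(phi_grid), dtype=float)
    c_A_grid = np.asarray(sorted(c_A_grid), dtype=float)
    p_flex_grid = np.asarray(sorted(p_flex_grid), dtype=float)
    points = []
    rows = []
    for i, phi in enumerate(phi_grid):
        for j, c_A in enumerate(c_A_grid):
            for k, pf in enumerate(p_flex_grid):
                pt = evaluate_phase_point(
                    phi, c_A, pf, L=L, n_replicates=n_replicates,
                    base_seed=base_seed, indices=(i, j, k), **kw)
                points.append(pt)
                rows.append({
                    "phi_tot": phi, "c_A": c_A, "p_flex": pf,
                    "n_rep": pt.call.n_replicates,
                    "n_perc_A": sum(a for a, _ in pt.call.replicates),
                    "n_perc_B": sum(b for _, b in pt.call.replicates),
                    "verdict": pt.verdict, "failures": pt.failures})
    table = pd.DataFrame(rows)

    crit_flex = []
    for (phi, c_A), grp in table.groupby(["phi_tot", "c_A"]):
        grp = grp.sort_values("p_flex")
        bigel = grp[grp.verdict == BIGEL]
        crit_flex.append({"phi_tot": phi, "c_A": c_A,
                          "p_flex_c": bigel.p_flex.iloc[0] if len(bigel) else np.nan})
    crit_conc = []
    for (phi, pf), grp in table.groupby(["phi_tot", "p_flex"]):
        grp = grp.sort_values("c_A")
        bigel = grp[grp.verdict == BIGEL]
        crit_conc.append({"phi_tot": phi, "p_flex": pf,
                          "c_A_c": bigel.c_A.iloc[0] if len(bigel) else np.nan})

    violations = []
    for (phi, pf), grp in table.groupby(["phi_tot", "p_flex"]):
        v = (grp.sort_values("c_A").verdict == BIGEL).to_numpy()
        # expect a single fluid->bigel transition along increasing c_A
        if np.any(np.diff(v.astype(int)) < 0):
            violations.append(("c_A", phi, pf))
    return StateDiagram(points=points, table=table,
                        critical_flexibility=pd.DataFrame(crit_flex),
                        critical_concentration=pd.DataFrame(crit_conc),
                        monotonicity_violations=violations)


def plot_state_diagram(diagram: StateDiagram, ax=None):
    """Heat map of the critical flexibility over (c_A, phi_tot).

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    table = diagram.critical_flexibility.pivot(index="phi_tot", columns="c_A",
                                               values="p_flex_c")
    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(table.columns, table.index, table.to_numpy(),
                         shading="nearest", cmap="viridis", vmin=0.0, vmax=1.0)
    ax.figure.colorbar(mesh, ax=ax, label=r"critical flexibility $p_{flex}^c$")
    ax.set_xlabel(r"$c_A$")
    ax.set_ylabel(r"$\phi_{tot}$")
    return ax
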