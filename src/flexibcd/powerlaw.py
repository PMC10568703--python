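"""Log-binned power-law exponent fits.

All exponents reported by the package (fractal dimension d_f from
``m ~ Rg^d_f``, size-distribution exponent tau from ``N(m) ~ m^-tau``,
backbone scaling d_f/d_b from ``m ~ l^(d_f/d_b)``) come through one
protocol: logarithmic binning at 4 bins per decade, ordinary least
squares on the bin medians (bin-average densities for histograms).  The
fit window and point count are recorded on the result so every exponent
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BINS_PER_DECADE = 4


@dataclass
class PowerLawFit:
    """An exponent estimate with its provenance."""

    exponent: float
    stderr: float
    fit_range: tuple[float, float]
    n_points: int  # populated log-bins entering the fit
    n_samples: int  # raw (x, y) pairs inside the window
    reliable: bool
    note: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = "" if self.reliable else " [unreliable]"
        return (f"exponent {self.exponent:.3f} +- {self.stderr:.3f} "
                f"({self.n_points} bins over {self.fit_range}){flag}")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error from ordinary least squares."""
    n = len(x)
    A = np.stack([x, np.ones(n)], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    if n > 2:
        resid = y - A @ coef
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        stderr = np.sqrt(s2 / sxx) if sxx > 0 else np.inf
    else:
        stderr = np.inf
    return slope, stderr


def _log_bin_edges(lo: float, hi: float) -> np.ndarray:
    lo10, hi10 = np.log10(lo), np.log10(hi)
    n = max(1, int(np.ceil((hi10 - lo10) * BINS_PER_DECADE)))
    return np.logspace(lo10, hi10, n + 1)


def fit_loglog_medians(x, y, x_range=None, min_bins: int = 5) -> PowerLawFit:
    """Slope of ``log y`` vs ``log x`` over log-binned medians.

    Pairs are binned in ``x`` at 4 bins/decade inside ``x_range``;
    each populated bin contributes (median log x, median log y).
    The fit is flagged unreliable with fewer than ``min_bins`` populated
    bins or less than one decade of dynamic range in ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[ok], y[ok]
    if x_range is not None:
        sel = (x >= x_range[0]) & (x <= x_range[1])
        x, y = x[sel], y[sel]
    if len(x) < 2 or x.min() == x.max():
        return PowerLawFit(np.nan, np.inf, (np.nan, np.nan), 0, len(x), False,
                           "no dynamic range")
    edges = _log_bin_edges(x.min(), x.max() * (1 + 1e-12))
    which = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    bx, by = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            bx.append(np.median(np.log10(x[sel])))
            by.append(np.median(np.log10(y[sel])))
    bx = np.asarray(bx)
    by = np.asarray(by)
    slope, stderr = _ols(bx, by)
    decades = np.log10(x.max() / x.min())
    reliable = len(bx) >= min_bins and decades >= 1.0
    note = "" if reliable else f"{len(bx)} bins over {decades:.2f} decades"
    return PowerLawFit(slope, stderr, (float(x.min()), float(x.max())),
                       len(bx), len(x), reliable, note)


def fit_fractal_dimension(masses, rgs, fit_range=None) -> PowerLawFit:
    """Fractal dimension d_f from ``m ~ Rg^d_f``.

    Clusters are log-binned by *mass* (masses span more decades than Rg
    when d_f > 1, so mass bins resolve the scaling better); each populated
    bin contributes its median log m and median log Rg, and d_f is the OLS
    slope of log m on log Rg.  ``fit_range`` restricts the mass window; the
    default ``[10, max_mass / 3]`` stays clear of monomer-scale clusters
    and the finite-size cutoff.  Spanning clusters (Rg = nan) drop out.
    """
    masses = np.asarray(masses, dtype=float)
    rgs = np.asarray(rgs, dtype=float)
    ok = np.isfinite(rgs) & (rgs > 0) & (masses > 0)
    masses, rgs = masses[ok], rgs[ok]
    if masses.size == 0:
        return PowerLawFit(np.nan, np.inf, (np.nan, np.nan), 0, 0, False, "empty")
    if fit_range is None:
        fit_range = (10.0, max(30.0, masses.max() / 3.0))
    sel = (masses >= fit_range[0]) & (masses <= fit_range[1])
    m, rg = masses[sel], rgs[sel]
    if len(m) < 2 or m.min() == m.max():
        return PowerLawFit(np.nan, np.inf, tuple(fit_range), 0, len(m), False,
                           "no dynamic range")
    edges = _log_bin_edges(m.min(), m.max() * (1 + 1e-12))
    which = np.clip(np.digitize(m, edges) - 1, 0, len(edges) - 2)
    bx, by = [], []
    for b in range(len(edges) - 1):
        pick = which == b
        if pick.any():
            bx.append(np.median(np.log10(rg[pick])))
            by.append(np.median(np.log10(m[pick])))
    bx, by = np.asarray(bx), np.asarray(by)
    slope, stderr = _ols(bx, by)
    decades = np.log10(m.max() / m.min())
    reliable = len(bx) >= 5 and decades >= 1.0
    note = "" if reliable else f"{len(bx)} bins over {decades:.2f} decades in m"
    return PowerLawFit(slope, stderr, (float(m.min()), float(m.max())),
                       len(bx), len(m), reliable, note)


def fit_size_distribution_exponent(masses, fit_range=None,
                                   m_min: float = 5.0,
                                   method: str = "mle") -> PowerLawFit:
    """Exponent tau of ``N(m) ~ m^-tau exp(-m/m_c)``.

    Two estimators, chosen by ``method``:

    ``"mle"`` (default) — discrete maximum likelihood of the truncated
    power-law-with-cutoff on the raw masses.  The right tool for a
    homogeneous ensemble (one cutoff): binned log-log slopes carry a
    +0.1..0.15 cutoff bias there (measured on inverse-CDF ground
    truth), whereas the MLE recovers exponents in [1, 3] within +-0.1.

    ``"binned"`` — ordinary least squares on the log-binned,
    width-normalized histogram (4 bins/decade, the largest half-decade
    trimmed).  The right tool for *pooled* ensembles mixing several
    cutoffs (e.g. histograms accumulated while the cutoff grows): the
    mixture is not a single power-law-with-cutoff, the MLE then reads
    its small-m bulk, and the binned slope — which weights all decades
    equally, like the guide-line slope of a log-log histogram plot —
    is the statistic the exponent refers to.

    Masses below ``m_min`` are excluded (small clusters are not in the
    scaling regime); ``fit_range`` overrides the window.  ``n_points``
    records the populated log-bins for auditability.
    """
    from scipy.optimize import minimize

    masses = np.asarray(masses, dtype=float)
    masses = masses[np.isfinite(masses) & (masses > 0)]
    if masses.size == 0:
        return PowerLawFit(np.nan, np.inf, (np.nan, np.nan), 0, 0, False, "empty")
    if fit_range is None:
        if method == "binned":
            fit_range = (m_min, masses.max() / np.sqrt(10.0))
        else:
            fit_range = (m_min, np.inf)
    lo, hi = fit_range
    msel = masses[(masses >= lo) & (masses <= hi)]
    if msel.size < 10 or msel.min() == msel.max():
        return PowerLawFit(np.nan, np.inf, (float(lo), float(hi)), 0,
                           len(msel), False, "no dynamic range")
    if method == "binned":
        edges = _log_bin_edges(msel.min(), msel.max() * (1 + 1e-12))
        counts, _ = np.histogram(msel, bins=edges)
        # integer sizes covered per bin (bins are half-open)
        widths = np.floor(edges[1:] - 1e-9) - np.ceil(edges[:-1] - 1e-9) + 1
        widths = np.maximum(widths, 1.0)
        centers = np.sqrt(edges[:-1] * edges[1:])
        pop = counts > 0
        if pop.sum() < 3:
            return PowerLawFit(np.nan, np.inf, (float(lo), float(hi)),
                               int(pop.sum()), len(msel), False,
                               "too few populated bins")
        slope, stderr = _ols(np.log10(centers[pop]),
                             np.log10(counts[pop] / widths[pop]))
        decades = np.log10(msel.max() / msel.min())
        reliable = pop.sum() >= 5 and decades >= 1.0
        note = "" if reliable else f"{int(pop.sum())} bins over {decades:.2f} decades"
        return PowerLawFit(-slope, stderr, (float(msel.min()), float(msel.max())),
                           int(pop.sum()), len(msel), reliable, note)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    m_lo = int(np.ceil(msel.min()))
    m_top = int(max(4 * msel.max(), 100))
    support = np.arange(m_lo, m_top + 1, dtype=float)
    log_support = np.log(support)
    n = len(msel)
    sum_log = float(np.log(msel).sum())
    sum_m = float(msel.sum())

    def nll(theta):
        tau, log_mc = theta
        mc = np.exp(log_mc)
        logw = -tau * log_support - support / mc
        z = np.logaddexp.reduce(logw)
        return tau * sum_log / n + sum_m / (mc * n) + z

    best = None
    for tau0 in (1.2, 2.0, 2.8):
        res = minimize(nll, x0=(tau0, np.log(max(10.0, msel.max()))),
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    tau_hat = float(best.x[0])
    # observed-information stderr via a central second difference in tau
    eps = 1e-3
    f0 = nll(best.x)
    fp = nll(best.x + np.array([eps, 0.0]))
    fm = nll(best.x - np.array([eps, 0.0]))
    curv = n * (fp + fm - 2 * f0) / eps**2
    stderr = float(1.0 / np.sqrt(curv)) if curv > 0 else np.inf

    edges = _log_bin_edges(msel.min(), msel.max() * (1 + 1e-12))
    counts, _ = np.histogram(msel, bins=edges)
    n_bins = int((counts > 0).sum())
    decades = np.log10(msel.max() / msel.min())
    reliable = n_bins >= 5 and decades >= 1.0
    note = "" if reliable else f"{n_bins} bins over {decades:.2f} decades"
    return PowerLawFit(tau_hat, stderr, (float(msel.min()), float(msel.max())),
                       n_bins, n, reliable, note)


def fit_backbone_scaling(masses, chem_lengths) -> PowerLawFit:
    """Backbone exponent d_f/d_b from ``m ~ l^(d_f/d_b)``."""
    return fit_loglog_medians(chem_lengths, masses)
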