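"""Posterior and population statistics of the rate estimates.

Covers per-cell summaries (mean/SD/CV/SNR of the active rate, switch-time
spread), sorted rate "stack" densities, per-construct population
statistics and fold changes, log-normality testing of single-cell mean
rates, ECDFs in log space, noise-mean trends, gamma fits to per-cell rate
SDs, containment ("filter") metrics, and the four-class behaviour
classification of single-cell rate posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PosteriorChains
from .errors import ConfigurationError, DataError

BEHAVIOR_CLASSES = ("fast-high", "fast-low", "slow-wide", "multimodal")


@dataclass
class RateStack:
    """Per-cell posterior rate densities on a common grid.

    ``density`` has shape (n_cells, n_grid); rows are sorted ascending by
    posterior mean rate and each integrates to one on the grid (trapezoid).
    """

    grid: np.ndarray
    density: np.ndarray
    cell_ids: list
    means: np.ndarray

    def __post_init__(self) -> None:
        integrals = np.trapezoid(self.density, self.grid, axis=1)
        if np.any(np.abs(integrals - 1.0) > 1e-6):
            raise DataError("stack rows must integrate to 1 on the grid")
        if np.any(np.diff(self.means) < 0):
            raise DataError("stack cells must be sorted by ascending mean")


def summarize_cells(
    chains: PosteriorChains,
    rate: str = "tau1",
    multimodal_flag: bool = True,
) -> pd.DataFrame:
    """Per-cell posterior summaries of the chosen rate and the switch time.

    Columns: cell_id, construct_id, mean, sd, cv, snr, snr_defined,
    switch_median, switch_width90, multimodal.  Switch-time spread is the
    central 90% interval width of the T posterior; CV = SD/mean and
    SNR = 1/CV (flagged undefined for degenerate posteriors).
    """
    if chains.cell_params.shape[1] == 0:
        raise DataError("no retained samples")
    rows = []
    for i, cid in enumerate(chains.cell_ids):
        s = chains.samples(rate, i)
        t = chains.samples("T", i)
        mean = float(np.mean(s))
        sd = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
        cv = sd / mean if mean > 0 else np.nan
        defined = bool(np.isfinite(cv) and cv > 0)
        q05, q50, q95 = np.quantile(t, [0.05, 0.5, 0.95])
        rows.append({
            "cell_id": cid,
            "construct_id": chains.constructs[i],
            "mean": mean, "sd": sd, "cv": cv,
            "snr": 1.0 / cv if defined else np.nan,
            "snr_defined": defined,
            "switch_median": float(q50),
            "switch_width90": float(q95 - q05),
            "multimodal": _is_multimodal(s) if multimodal_flag else False,
        })
    return pd.DataFrame(rows)


def centered_switch_samples(chains: PosteriorChains, cell: int) -> np.ndarray:
    """Switch-time samples centered on their median, for cross-cell display."""
    t = chains.samples("T", cell)
    return t - np.median(t)


def build_rate_stack(
    chains: PosteriorChains,
    grid: Optional[np.ndarray] = None,
    rate: str = "tau1",
    n_grid: int = 200,
) -> RateStack:
    """Kernel densities of every cell's rate posterior on a shared grid.

    Bandwidths follow Silverman's rule on log-rate samples and densities
    are computed on a log-spaced grid, then renormalized so each row
    integrates to one; cells are sorted ascending by posterior mean.
    """
    all_s = [chains.samples(rate, i) for i in range(chains.n_cells)]
    lo = min(float(s.min()) for s in all_s)
    hi = max(float(s.max()) for s in all_s)
    if grid is None:
        grid = np.geomspace(lo * 0.8, hi * 1.25, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] > lo or grid[-1] < hi:
            raise ConfigurationError(
                f"grid [{grid[0]:g}, {grid[-1]:g}] does not cover the sampled "
                f"rate range [{lo:g}, {hi:g}]")
    means = np.array([float(np.mean(s)) for s in all_s])
    order = np.argsort(means, kind="stable")
    dens = np.empty((chains.n_cells, grid.size))
    logg = np.log(grid)
    for row, i in enumerate(order):
        ls = np.log(all_s[i])
        if np.ptp(ls) < 1e-12:
            # degenerate posterior: narrow Gaussian bump at the point mass
            d = stats.norm.pdf(logg, ls[0], 1e-3) / grid
        else:
            kde = stats.gaussian_kde(ls, bw_method="silverman")
            d = kde(logg) / grid
        area = np.trapezoid(d, grid)
        if area <= 0:
            raise DataError(f"zero density mass for cell {chains.cell_ids[i]}")
        dens[row] = d / area
    return RateStack(
        grid=grid, density=dens,
        cell_ids=[chains.cell_ids[i] for i in order],
        means=means[order],
    )


def population_stats(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per construct: unweighted mean and sample SD of the single-cell
    posterior mean rates, plus the cell count."""
    out = []
    for construct, grp in summaries.groupby("construct_id", sort=False):
        if len(grp) < 2:
            raise DataError(
                f"construct {construct!r} has {len(grp)} cell(s); need >= 2")
        out.append({
            "construct_id": construct,
            "mean": float(grp["mean"].mean()),
            "sd": float(grp["mean"].std(ddof=1)),
            "n_cells": int(len(grp)),
        })
    return pd.DataFrame(out).set_index("construct_id")


def fold_change(stats_a, stats_b) -> float:
    """Ratio of population mean rates, construct A over construct B."""
    a = float(stats_a["mean"]) if hasattr(stats_a, "__getitem__") else float(stats_a)
    b = float(stats_b["mean"]) if hasattr(stats_b, "__getitem__") else float(stats_b)
    if b <= 0:
        raise DataError("denominator population mean must be > 0")
    return a / b


def _ks_normal_rows(x: np.ndarray) -> np.ndarray:
    """KS distance to a normal with per-row estimated mean/SD; x is (B, n)."""
    n = x.shape[1]
    m = x.mean(axis=1, keepdims=True)
    s = x.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((x - m) / s, axis=1)
    cdf = stats.norm.cdf(z)
    up = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return np.maximum((up - cdf).max(axis=1), (cdf - lo).max(axis=1))


class LognormalityResult(NamedTuple):
    statistic: float
    pvalue: float          # parametric-bootstrap (Lilliefors-style)
    pvalue_naive: float    # KS p ignoring parameter estimation
    n: int


def lognormality_ks(
    means: np.ndarray,
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> LognormalityResult:
    """Test log-normality of single-cell mean rates.

    The KS distance of log-means to a normal with estimated parameters is
    calibrated by a parametric bootstrap (estimating parameters inflates
    naive KS p-values); the naive p is reported alongside.
    """
    means = np.asarray(means, dtype=float)
    if means.size < 8:
        raise DataError("need at least 8 cells for the log-normality test")
    if np.any(means <= 0):
        raise DataError("nonpositive mean rate in log-normality test")
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.log(means)
    d_obs = float(_ks_normal_rows(x[None, :])[0])
    mu, sd = x.mean(), x.std(ddof=1)
    p_naive = float(stats.kstest(x, "norm", args=(mu, sd)).pvalue)
    # D with estimated location/scale is pivotal: bootstrap from N(0, 1)
    d_boot = _ks_normal_rows(rng.standard_normal((n_boot, x.size)))
    p_boot = (1.0 + np.sum(d_boot >= d_obs)) / (n_boot + 1.0)
    return LognormalityResult(d_obs, float(p_boot), p_naive, int(x.size))


def log_ecdf(means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF of log mean rates: returns (log-means sorted,
    cumulative probabilities i/n)."""
    means = np.asarray(means, dtype=float)
    if means.size == 0:
        raise DataError("empty input to log_ecdf")
    if np.any(means <= 0):
        raise DataError("nonpositive mean rate in log_ecdf")
    x = np.sort(np.log(means))
    return x, np.arange(1, x.size + 1) / x.size


class TrendResult(NamedTuple):
    sd_slope: float
    sd_intercept: float
    cv_slope: float
    cv_intercept: float
    sd_slope_positive: bool
    cv_slope_negative: bool


def cv_mean_trend(summaries: pd.DataFrame) -> TrendResult:
    """Ordinary least squares of intracellular SD and CV against the mean
    rate across cells (the noise-mean relationship)."""
    import statsmodels.api as sm

    if len(summaries) < 3:
        raise DataError("need >= 3 cells for a trend fit")
    mean = summaries["mean"].to_numpy(dtype=float)
    if np.ptp(mean) == 0:
        raise DataError("all mean rates equal; trend is degenerate")
    X = sm.add_constant(mean)
    fit_sd = sm.OLS(summaries["sd"].to_numpy(dtype=float), X).fit()
    fit_cv = sm.OLS(summaries["cv"].to_numpy(dtype=float), X).fit()
    return TrendResult(
        sd_slope=float(fit_sd.params[1]), sd_intercept=float(fit_sd.params[0]),
        cv_slope=float(fit_cv.params[1]), cv_intercept=float(fit_cv.params[0]),
        sd_slope_positive=bool(fit_sd.params[1] > 0),
        cv_slope_negative=bool(fit_cv.params[1] < 0),
    )


def fit_sd_gamma(sds_by_group: dict) -> pd.DataFrame:
    """Maximum-likelihood gamma fits to per-cell rate SDs, per group.

    Returns shape, scale, fitted mean (shape*scale) and n per group; used
    to compare estimate uncertainty across construct classes.
    """
    rows = []
    for group, sds in sds_by_group.items():
        sds = np.asarray(sds, dtype=float)
        if sds.size < 10:
            raise DataError(f"group {group!r}: need >= 10 SDs, got {sds.size}")
        if np.any(sds <= 0):
            raise DataError(f"group {group!r}: nonpositive SD")
        if np.ptp(sds) == 0:
            raise DataError(f"group {group!r}: constant sample (zero variance)")
        shape, _, scale = stats.gamma.fit(sds, floc=0)
        rows.append({"group": group, "shape": float(shape),
                     "scale": float(scale),
                     "fitted_mean": float(shape * scale), "n": int(sds.size)})
    return pd.DataFrame(rows).set_index("group")


def containment_fraction(
    samples_a: Sequence[np.ndarray],
    samples_b: Sequence[np.ndarray],
    level: float = 0.9,
) -> float:
    """Fraction of A cells whose central rate interval lies inside the
    interval of the quantile-matched B cell.

    Cells in each group are sorted by posterior mean and matched by
    quantile rank; containment compares closed central ``level`` posterior
    intervals.  This quantifies the "filter" action of a regulatory module
    narrowing the intracellular rate range of its basal promoter.
    """
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise DataError("both groups must be nonempty")
    qlo, qhi = (1 - level) / 2, 1 - (1 - level) / 2
    a_sorted = sorted(samples_a, key=lambda s: float(np.mean(s)))
    b_sorted = sorted(samples_b, key=lambda s: float(np.mean(s)))
    nb = len(b_sorted)
    contained = 0
    for i, sa in enumerate(a_sorted):
        q = (i + 0.5) / len(a_sorted)
        sb = b_sorted[min(nb - 1, int(q * nb))]
        alo, ahi = np.quantile(sa, [qlo, qhi])
        blo, bhi = np.quantile(sb, [qlo, qhi])
        if alo >= blo and ahi <= bhi:
            contained += 1
    return contained / len(a_sorted)


def _is_multimodal(samples: np.ndarray, ic_margin: float = 10.0) -> bool:
    """Two-component vs one-component Gaussian mixture on log samples,
    decided by a BIC margin."""
    from sklearn.mixture import GaussianMixture

    s = np.log(samples[samples > 0])
    if s.size < 100 or np.ptp(s) < 1e-9:
        return False
    if s.size > 1000:
        s = s[:: s.size // 1000 + 1]
    X = s[:, None]
    bic1 = GaussianMixture(1, random_state=0).fit(X).bic(X)
    bic2 = GaussianMixture(2, random_state=0, n_init=3).fit(X).bic(X)
    return bool(bic1 - bic2 > ic_margin)


def classify_behavior(
    rate_samples: np.ndarray,
    switch_samples: np.ndarray,
    cohort_cv_q75: float,
    cohort_mean_median: float,
    ic_margin: float = 10.0,
) -> str:
    """Assign one of the four promoter behaviour classes to a cell.

    multimodal if a two-component mixture beats one component by the BIC
    margin; else slow-wide if the cell's CV exceeds the cohort upper
    quartile; else fast-high / fast-low by mean rate against the cohort
    median.  Rapid rate acquisition shows as a narrow switch-time spread
    alongside low CV, which the fast classes capture.
    """
    rate_samples = np.asarray(rate_samples, dtype=float)
    if rate_samples.size < 100:
        raise DataError("need >= 100 retained samples to classify")
    if _is_multimodal(rate_samples, ic_margin):
        return "multimodal"
    mean = float(np.mean(rate_samples))
    sd = float(np.std(rate_samples, ddof=1))
    cv = sd / mean if mean > 0 else np.inf
    if cv > cohort_cv_q75:
        return "slow-wide"
    return "fast-high" if mean >= cohort_mean_median else "fast-low"


def classify_cohort(chains: PosteriorChains, rate: str = "tau1") -> pd.Series:
    """Classify every cell against its own cohort's thresholds."""
    samples = [chains.samples(rate, i) for i in range(chains.n_cells)]
    means = np.array([np.mean(s) for s in samples])
    cvs = np.array([np.std(s, ddof=1) / m if m > 0 else np.inf
                    for s, m in zip(samples, means)])
    q75 = float(np.quantile(cvs, 0.75))
    med = float(np.median(means))
    labels = [
        classify_behavior(samples[i], chains.samples("T", i), q75, med)
        for i in range(chains.n_cells)
    ]
    return pd.Series(labels, index=chains.cell_ids, name="behavior")
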