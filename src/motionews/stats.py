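"""Association and distribution statistics for EWS and reaction times.

Two analyses live here.  The first relates per-trial early-warning
times to motion-onset times: a 2-D kernel-density filter trims
low-density outliers (false-positive detections), then ordinary least
squares of onset time on EWS time yields an intercept Delta-t — the
average lead of the warning signal over the onset when the slope is
near one.  The second compares two reaction-time samples with the
Mann-Whitney rank-sum test (with rank-biserial effect size), the
two-sample Kolmogorov-Smirnov test, and a shift function of decile
differences (Harrell-Davis decile estimates of one arm minus the
other), which localizes where along the distribution an effect acts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import betainc

__all__ = [
    "DeltaRegression",
    "RTComparison",
    "density_filter",
    "delta_regression",
    "harrell_davis_quantile",
    "harrell_davis_deciles",
    "rt_compare",
]

DECILES = np.arange(0.1, 0.91, 0.1)


@dataclass
class DeltaRegression:
    """Density-filtered regression of onset times on EWS times.

    ``intercept_ms`` is Delta-t, the average lead of the EWS event over
    the onset event when the slope is close to 1; ``mean_diff_ms`` (the
    plain mean of onset minus EWS over the retained points) is reported
    alongside as a robustness readout.
    """

    slope: float
    intercept_ms: float
    slope_se: float
    intercept_se: float
    retained_fraction: float
    mask: np.ndarray
    coverage_target: float
    mean_diff_ms: float
    n_input: int
    n_used: int
    density_fallback: bool = False


@dataclass
class RTComparison:
    """Two-sample reaction-time comparison.

    ``decile_diffs`` holds the nine decile differences (b minus a), in
    the units of the inputs.  ``degenerate`` flags all-tied input where
    the rank tests are uninformative.
    """

    u_stat: float
    p_mw: float
    effect_size: float
    ks_stat: float
    p_ks: float
    decile_diffs: np.ndarray
    n_a: int
    n_b: int
    degenerate: bool = False


def density_filter(
    x: np.ndarray, y: np.ndarray, coverage: float
) -> tuple[np.ndarray, bool]:
    """Retain the points inside the density contour covering ``coverage``.

    A Gaussian kernel density estimate (plug-in bandwidth) is evaluated
    at every point; the retained set is the super-level set of the
    density containing approximately the requested fraction of points
    (the level is the empirical (1 - coverage) quantile of the point
    densities).  Degenerate clouds (singular covariance) retain all
    points, flagged by the second return value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 10:
        raise ValueError(f"need at least 10 points, got {x.size}")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if coverage == 1.0:
        return np.ones(x.size, dtype=bool), False
    xy = np.vstack([x, y])
    try:
        kde = sps.gaussian_kde(xy)
        dens = kde(xy)
    except np.linalg.LinAlgError:
        warnings.warn(
            "degenerate point cloud: density filter retained all points",
            stacklevel=2,
        )
        return np.ones(x.size, dtype=bool), True
    level = np.quantile(dens, 1.0 - coverage)
    return dens >= level, False


def delta_regression(
    ews_times: Sequence[float],
    onset_times: Sequence[float],
    coverage: float = 0.81,
    min_ews_time: Optional[float] = None,
) -> DeltaRegression:
    """Delta-t between EWS events and motion onsets, by filtered OLS.

    Pairs with a missing value are dropped; when ``min_ews_time`` is
    given, EWS detections earlier than that time (seconds from trial
    start) are treated as false positives and excluded before
    filtering.  Times are in seconds; the intercept is reported in ms.
    """
    ews = np.array(
        [np.nan if v is None else float(v) for v in ews_times], dtype=float
    )
    onset = np.array(
        [np.nan if v is None else float(v) for v in onset_times], dtype=float
    )
    if ews.shape != onset.shape:
        raise ValueError("ews_times and onset_times must have equal length")
    n_input = ews.size
    valid = np.isfinite(ews) & np.isfinite(onset)
    if min_ews_time is not None:
        valid &= ews >= min_ews_time
    if valid.sum() < 10:
        raise ValueError(
            f"only {int(valid.sum())} usable pairs; need at least 10"
        )
    keep, fallback = density_filter(ews[valid], onset[valid], coverage)
    mask = np.zeros(n_input, dtype=bool)
    mask[np.flatnonzero(valid)[keep]] = True
    if mask.sum() < 10:
        raise ValueError("fewer than 10 points retained by the density filter")
    xr, yr = ews[mask], onset[mask]
    fit = sm.OLS(yr, sm.add_constant(xr)).fit()
    return DeltaRegression(
        slope=float(fit.params[1]),
        intercept_ms=float(fit.params[0] * 1000.0),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0] * 1000.0),
        retained_fraction=float(mask.sum() / valid.sum()),
        mask=mask,
        coverage_target=float(coverage),
        mean_diff_ms=float(np.mean(yr - xr) * 1000.0),
        n_input=n_input,
        n_used=int(mask.sum()),
        density_fallback=fallback,
    )


def harrell_davis_quantile(x: np.ndarray, q: float) -> float:
    """Harrell-Davis quantile estimate: a beta-weighted mean of order stats."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    a = (n + 1) * q
    b = (n + 1) * (1.0 - q)
    i = np.arange(1, n + 1)
    w = betainc(a, b, i / n) - betainc(a, b, (i - 1) / n)
    return float(np.sum(w * x))


def harrell_davis_deciles(x: np.ndarray) -> np.ndarray:
    """The nine Harrell-Davis decile estimates of a sample."""
    return np.array([harrell_davis_quantile(x, q) for q in DECILES])


def rt_compare(
    rt_a: Sequence[float],
    rt_b: Sequence[float],
    quantile_method: str = "harrell-davis",
) -> RTComparison:
    """Compare two reaction-time samples.

    Runs the two-sided Mann-Whitney rank-sum test (U of the first
    sample, with rank-biserial effect size ``1 - 2U/(n_a n_b)``), the
    two-sample Kolmogorov-Smirnov test, and the shift function of
    decile differences (second minus first sample).  ``quantile_method``
    selects the Harrell-Davis decile estimator (default) or the simple
    empirical quantile.
    """
    a = np.asarray(rt_a, dtype=float)
    b = np.asarray(rt_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each arm needs at least 5 values")
    if quantile_method in ("harrell-davis", "hd"):
        dec = harrell_davis_deciles(b) - harrell_davis_deciles(a)
    elif quantile_method == "simple":
        dec = np.quantile(b, DECILES) - np.quantile(a, DECILES)
    else:
        raise ValueError(f"unknown quantile_method {quantile_method!r}")
    pooled = np.concatenate([a, b])
    degenerate = bool(np.all(pooled == pooled[0]))
    if degenerate:
        u = a.size * b.size / 2.0
        p_mw, ks, p_ks = 1.0, 0.0, 1.0
    else:
        u, p_mw = sps.mannwhitneyu(a, b, alternative="two-sided")
        ks_res = sps.ks_2samp(a, b)
        ks, p_ks = ks_res.statistic, ks_res.pvalue
    effect = 1.0 - 2.0 * u / (a.size * b.size)
    return RTComparison(
        u_stat=float(u),
        p_mw=float(p_mw),
        effect_size=float(effect),
        ks_stat=float(ks),
        p_ks=float(p_ks),
        decile_diffs=dec,
        n_a=int(a.size),
        n_b=int(b.size),
        degenerate=degenerate,
    )
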