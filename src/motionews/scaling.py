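"""Variance-divergence extraction and power-law exponent fitting.

Approaching a fold transition, quasi-static theory predicts the
fluctuation variance to diverge as

    sigma^2  ~  (t* - t)^(-1/2),

whereas pitchfork or Hopf transitions give exponent -1, so the fitted
exponent identifies the bifurcation type.  The pipeline mirrors the
windowed-variance treatment: detect the divergence point T* (first
threshold crossing of the windowed variance), cut the curve 100 ms
before and after T*, average curves within blocks of trials
synchronized on T*, then fit

    log(sigma^2) = -log(b) + n * log(t* - t)

by nonlinear least squares on 48-ms sub-windows offset by 4 ms over the
approach side of the curve, keeping the best fit (lowest SSE per point)
across sub-windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from motionews.ews import EWSSeries

__all__ = [
    "DivergenceCurve",
    "PowerLawFit",
    "baseline_max_threshold",
    "extract_divergence_curve",
    "average_block_curves",
    "fit_powerlaw",
    "median_exponent",
]


@dataclass
class DivergenceCurve:
    """Windowed-variance curve around a divergence point.

    ``t`` is time relative to the detected divergence point T* (so 0
    marks the threshold crossing); ``var`` the variance values.
    ``truncated`` flags curves clipped by a trial edge; ``n_trials`` the
    number of trials averaged into the curve.
    """

    t: np.ndarray
    var: np.ndarray
    tstar_detect: float
    truncated: bool = False
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.t.shape != self.var.shape:
            raise ValueError("t and var must have equal length")


@dataclass
class PowerLawFit:
    """Best power-law fit of a variance-divergence curve.

    ``n`` is the scaling exponent (-0.5 expected for a fold transition),
    ``b`` the scale parameter, ``tstar_fit`` the fitted critical time on
    the curve's (divergence-relative) clock, ``sse`` the summed squared
    log-variance residual of the winning sub-window and ``sse_per_point``
    the per-point value used to rank sub-windows.
    """

    b: float
    n: float
    tstar_fit: float
    sse: float
    sse_per_point: float
    window_index: int
    n_points: int
    diagnostics: dict = field(default_factory=dict)


def baseline_max_threshold(
    series: Sequence[EWSSeries], baseline_ms: float = 100.0
) -> float:
    """Divergence threshold from early-trial variance levels.

    Returns the maximum windowed variance observed among window centers
    within the first ``baseline_ms`` of each trial, across all trials —
    the data-driven rule for setting the variance-divergence threshold
    when no absolute level is meaningful for the signal's units.
    """
    best = -np.inf
    for s in series:
        m = s.t <= s.t[0] + baseline_ms / 1000.0
        if m.any():
            v = s.var[m]
            v = v[np.isfinite(v)]
            if v.size:
                best = max(best, float(v.max()))
    if not np.isfinite(best):
        raise ValueError("no finite baseline variance found")
    return best


def extract_divergence_curve(
    s: EWSSeries, threshold: float, half_width_ms: float = 100.0
) -> Optional[DivergenceCurve]:
    """Cut the variance curve around its first threshold crossing.

    Returns None when the variance never exceeds ``threshold``; the
    curve is flagged ``truncated`` when a trial edge clips the
    +-``half_width_ms`` span.
    """
    with np.errstate(invalid="ignore"):
        idx = np.flatnonzero(s.var > threshold)
    if idx.size == 0:
        return None
    tstar = float(s.t[idx[0]])
    half = half_width_ms / 1000.0
    mask = (s.t >= tstar - half - 1e-12) & (s.t <= tstar + half + 1e-12)
    truncated = bool(s.t[0] > tstar - half + 1e-12 or s.t[-1] < tstar + half - 1e-12)
    return DivergenceCurve(
        t=s.t[mask] - tstar, var=s.var[mask], tstar_detect=tstar,
        truncated=truncated,
    )


def _grid_step(curves: Sequence[DivergenceCurve]) -> float:
    steps = [np.min(np.diff(c.t)) for c in curves if c.t.size >= 2]
    if not steps:
        raise ValueError("curves too short to infer a time grid")
    return float(min(steps))


def average_block_curves(
    curves: Sequence[Optional[DivergenceCurve]], block_size: int = 30
) -> tuple[list[DivergenceCurve], int]:
    """Average divergence curves in consecutive blocks, aligned on T*.

    Curves are aligned on their divergence point (t = 0) and averaged
    pointwise on the common grid; entries that are None (no divergence
    detected in that trial) are excluded and counted.  Returns the list
    of block-averaged curves and the number of excluded trials.
    """
    if len(curves) == 0:
        raise ValueError("no curves to average")
    if block_size < 1:
        raise ValueError("block_size must be at least 1")
    n_excluded = sum(c is None for c in curves)
    out: list[DivergenceCurve] = []
    for start in range(0, len(curves), block_size):
        block = [c for c in curves[start : start + block_size] if c is not None]
        if not block:
            continue
        step = _grid_step(block)
        acc: dict[int, list[float]] = {}
        for c in block:
            for ti, vi in zip(c.t, c.var):
                acc.setdefault(int(round(ti / step)), []).append(float(vi))
        keys = sorted(acc)
        t = np.array([k * step for k in keys])
        var = np.array([np.mean(acc[k]) for k in keys])
        out.append(
            DivergenceCurve(
                t=t, var=var, tstar_detect=float("nan"),
                truncated=any(c.truncated for c in block), n_trials=len(block),
            )
        )
    if not out:
        raise ValueError("every curve was excluded; nothing to average")
    return out, n_excluded


def _fit_segment(
    t: np.ndarray, logv: np.ndarray, grid: float
) -> Optional[tuple[float, float, float, float]]:
    """Fit log(var) = -log(b) + n*log(t*-t) on one segment.

    The model is linear in (-log b, n) once t* is fixed, so the fit
    profiles out the linear pair and searches the 1-D SSE profile over
    t*: a log-spaced scan of candidate offsets past the segment end
    (keeping the log argument positive throughout) followed by a local
    bounded refinement around the best candidate.  Returns
    (b, n, tstar, sse), or None on a degenerate segment.
    """
    t_end = float(t.max())
    span = t_end - float(t.min())

    def solve(tstar: float) -> tuple[float, float, float]:
        z = np.log(tstar - t)
        A = np.column_stack([np.ones_like(z), z])
        coef, _, _, _ = np.linalg.lstsq(A, logv, rcond=None)
        r = logv - A @ coef
        return float(coef[0]), float(coef[1]), float(r @ r)

    # offsets from just past the last point out to far beyond the
    # segment (where the model degenerates to a straight log-line)
    offsets = np.geomspace(grid * 0.25, max(10.0 * span, 0.5), 60)
    sses = np.array([solve(t_end + s)[2] for s in offsets])
    if not np.any(np.isfinite(sses)):
        return None
    k = int(np.nanargmin(sses))
    lo = offsets[max(0, k - 1)]
    hi = offsets[min(len(offsets) - 1, k + 1)]
    res = minimize_scalar(
        lambda s: solve(t_end + s)[2],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    s_best = float(res.x) if res.fun <= sses[k] else float(offsets[k])
    c0, n, sse = solve(t_end + s_best)
    return float(np.exp(-c0)), n, t_end + s_best, sse


def fit_powerlaw(
    curve: DivergenceCurve,
    subwindow_ms: float = 48.0,
    offset_ms: float = 4.0,
    min_points: int = 4,
) -> PowerLawFit:
    """Fit the variance-divergence power law on sliding sub-windows.

    Sub-windows of ``subwindow_ms`` advance in steps of ``offset_ms``
    over the approach side of the curve (points at or before the
    detected divergence, where the scaling regime lives); each is fitted
    in log space and the fit with the lowest SSE per point wins.
    Raises ``RuntimeError`` when no sub-window yields a usable fit.
    """
    pre = (curve.t <= 1e-12) & np.isfinite(curve.var) & (curve.var > 0)
    t = curve.t[pre]
    logv = np.log(curve.var[pre])
    if t.size < min_points:
        raise RuntimeError(
            f"only {t.size} valid pre-divergence points; need {min_points}"
        )
    grid = float(np.min(np.diff(t))) if t.size >= 2 else 1e-3
    sub_w = subwindow_ms / 1000.0
    step = offset_ms / 1000.0
    starts = np.arange(t[0], t[-1] - sub_w + grid * 0.5 + 1e-12, step)
    if starts.size == 0:
        starts = np.array([t[0]])
    best: Optional[PowerLawFit] = None
    seen: set[tuple[int, int]] = set()
    for wi, s0 in enumerate(starts):
        m = (t >= s0 - 1e-12) & (t <= s0 + sub_w + 1e-12)
        if m.sum() < min_points:
            continue
        key = (int(np.flatnonzero(m)[0]), int(m.sum()))
        if key in seen:  # identical point set under a shifted start
            continue
        seen.add(key)
        res = _fit_segment(t[m], logv[m], grid)
        if res is None:
            continue
        b, n, tstar, sse = res
        spp = sse / m.sum()
        if best is None or spp < best.sse_per_point:
            best = PowerLawFit(
                b=b, n=n, tstar_fit=tstar, sse=sse, sse_per_point=spp,
                window_index=wi, n_points=int(m.sum()),
            )
    if best is None:
        raise RuntimeError(
            "power-law fit failed to converge in every sub-window "
            f"({starts.size} positions tried)"
        )
    return best


def median_exponent(fits: Sequence[PowerLawFit], n_max: float = 1.5) -> float:
    """Median fitted exponent over fits with |n| below ``n_max``.

    The truncation discards pathological fits from degenerate
    sub-windows before summarizing the ensemble.
    """
    ns = [f.n for f in fits if np.isfinite(f.n) and abs(f.n) < n_max]
    if not ns:
        raise ValueError("no fits with |n| below the truncation level")
    return float(np.median(ns))
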