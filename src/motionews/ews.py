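"""Windowed early-warning-signal statistics and rise detectors.

Critical slowing down ahead of a fold transition shows up in a sliding
window as (i) a rise of the lag-1 autocorrelation AR(1), (ii) a rise of
the autocorrelation decay time tau (the first lag at which the windowed
autocorrelation falls to 1/e of its lag-0 value), and (iii) growth of
the variance.  All three are computed per window with the window mean as
the reference level:

    AR(1) = sum_i (v_i - v0)(v_{i-1} - v0) / sum_i (v_i - v0)^2
    R(m)  = sum_i (v_i - v0)(v_{i-m} - v0) / sum_i (v_i - v0)^2
    tau   = first integer lag m with R(m) <= 1/e   (reported in ms)
    var   = sum_i (v_i - v0)^2 / (n - 1)

Windows with zero fluctuation yield NaN for AR(1) and tau.  The rise
detectors return the center time of the first window satisfying each
threshold rule, or None.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WindowSpec",
    "EWSSeries",
    "window_centers",
    "windowed_ar1",
    "autocorr_decay_time",
    "windowed_variance",
    "compute_ews",
    "detect_ar1_rise",
    "detect_tau_rise",
    "detect_var_rise",
]

_INV_E = 1.0 / np.e


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for EWS extraction.

    ``length_ms`` is converted to a sample count by rounding
    ``length_ms * rate / 1000``; ``stride_ms=None`` means one sample.
    """

    length_ms: float = 40.0
    stride_ms: Optional[float] = None
    rate: float = 240.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.n_samples < 4:
            raise ValueError(
                f"window of {self.length_ms} ms at {self.rate} Hz has "
                f"{self.n_samples} samples; at least 4 are required"
            )
        if self.stride_samples < 1:
            raise ValueError("stride must be at least one sample")

    @property
    def n_samples(self) -> int:
        return int(round(self.length_ms * self.rate / 1000.0))

    @property
    def stride_samples(self) -> int:
        if self.stride_ms is None:
            return 1
        return int(round(self.stride_ms * self.rate / 1000.0))


@dataclass
class EWSSeries:
    """Windowed EWS statistics aligned to window-center times.

    ``tau`` is in milliseconds; ``var`` is in squared signal units.
    """

    t: np.ndarray
    ar1: np.ndarray
    tau: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.ar1) == len(self.tau) == len(self.var) == n):
            raise ValueError("EWSSeries arrays must share one length")


def _windows(v: np.ndarray, w: WindowSpec) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if v.size < w.n_samples:
        raise ValueError(
            f"series of {v.size} samples shorter than one window "
            f"({w.n_samples} samples)"
        )
    return sliding_window_view(v, w.n_samples)[:: w.stride_samples]


def window_centers(n_series: int, w: WindowSpec, t0: float = 0.0) -> np.ndarray:
    """Center times of each window over a series of ``n_series`` samples."""
    n_win = (n_series - w.n_samples) // w.stride_samples + 1
    starts = np.arange(n_win) * w.stride_samples
    return t0 + (starts + (w.n_samples - 1) / 2.0) / w.rate


def _demeaned(v, w):
    W = _windows(v, w)
    d = W - W.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", d, d)
    return d, denom


def windowed_ar1(v: np.ndarray, w: WindowSpec) -> np.ndarray:
    """Lag-1 autocorrelation per window; NaN for constant windows."""
    d, denom = _demeaned(v, w)
    num = np.einsum("ij,ij->i", d[:, 1:], d[:, :-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def autocorr_decay_time(v: np.ndarray, w: WindowSpec) -> np.ndarray:
    """Autocorrelation decay time per window, in milliseconds.

    The decay time is the first integer lag m (1 <= m < window length)
    at which the windowed autocorrelation R(m) drops to 1/e of its lag-0
    value; NaN if no lag within the window reaches the threshold, or if
    the window is constant.
    """
    d, denom = _demeaned(v, w)
    n = w.n_samples
    n_win = d.shape[0]
    ok = denom > 0
    safe = np.where(ok, denom, 1.0)
    crossed = np.zeros(n_win, dtype=bool)
    lag = np.zeros(n_win, dtype=int)
    for m in range(1, n):
        Rm = np.einsum("ij,ij->i", d[:, m:], d[:, :-m]) / safe
        hit = (~crossed) & (Rm <= _INV_E)
        lag[hit] = m
        crossed |= hit
        if crossed.all():
            break
    tau = np.where(crossed & ok, lag * 1000.0 / w.rate, np.nan)
    return tau


def windowed_variance(v: np.ndarray, w: WindowSpec) -> np.ndarray:
    """Unbiased (n-1 divisor) variance per window."""
    if w.n_samples < 2:
        raise ValueError("variance needs at least 2 samples per window")
    _, denom = _demeaned(v, w)
    return denom / (w.n_samples - 1)


def compute_ews(
    v: np.ndarray, w: WindowSpec, t0: float = 0.0
) -> EWSSeries:
    """All three windowed EWS statistics of a series in one pass.

    ``t0`` is the time of the first sample of ``v``; window-center times
    are reported on that clock.
    """
    v = np.asarray(v, dtype=float)
    return EWSSeries(
        t=window_centers(v.size, w, t0=t0),
        ar1=windowed_ar1(v, w),
        tau=autocorr_decay_time(v, w),
        var=windowed_variance(v, w),
    )


def _first_time(t: np.ndarray, hit: np.ndarray) -> Optional[float]:
    idx = np.flatnonzero(hit)
    return float(t[idx[0]]) if idx.size else None


def detect_ar1_rise(s: EWSSeries, threshold: float = 0.1) -> Optional[float]:
    """Time of the first window whose AR(1) exceeds ``threshold``."""
    with np.errstate(invalid="ignore"):
        return _first_time(s.t, s.ar1 > threshold)


def detect_tau_rise(s: EWSSeries, fold_change: float = 0.20) -> Optional[float]:
    """Time of the first >``fold_change`` jump of tau between consecutive windows.

    Only adjacent windows where both decay times are defined are
    considered; the reported time is that of the later window of the
    first qualifying pair.
    """
    tau = s.tau
    if np.isfinite(tau).sum() < 2:
        return None
    with np.errstate(invalid="ignore"):
        ratio = tau[1:] / tau[:-1]
        hit = np.isfinite(ratio) & (ratio - 1.0 > fold_change)
    idx = np.flatnonzero(hit)
    return float(s.t[idx[0] + 1]) if idx.size else None


def detect_var_rise(s: EWSSeries, threshold: float = 1.5e-4) -> Optional[float]:
    """Time of the first window whose variance exceeds ``threshold``."""
    with np.errstate(invalid="ignore"):
        return _first_time(s.t, s.var > threshold)
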