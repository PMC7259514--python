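"""Windowed EWS statistics: printed-formula oracles and detector rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionews.ews import (
    EWSSeries,
    WindowSpec,
    autocorr_decay_time,
    compute_ews,
    detect_ar1_rise,
    detect_tau_rise,
    detect_var_rise,
    window_centers,
    windowed_ar1,
    windowed_variance,
)

# ---------------------------------------------------------------------------
# Naive double-loop implementations of the printed formulas, kept
# deliberately independent of the vectorized code they check.


def naive_ar1(window):
    v0 = sum(window) / len(window)
    num = 0.0
    den = 0.0
    for i in range(len(window)):
        den += (window[i] - v0) ** 2
        if i >= 1:
            num += (window[i] - v0) * (window[i - 1] - v0)
    if den == 0:
        return float("nan")
    return num / den


def naive_tau(window, rate):
    v0 = sum(window) / len(window)
    den = sum((x - v0) ** 2 for x in window)
    if den == 0:
        return float("nan")
    for m in range(1, len(window)):
        num = 0.0
        for i in range(m, len(window)):
            num += (window[i] - v0) * (window[i - m] - v0)
        if num / den <= 1.0 / np.e:
            return m * 1000.0 / rate
    return float("nan")


def naive_var(window):
    v0 = sum(window) / len(window)
    return sum((x - v0) ** 2 for x in window) / (len(window) - 1)


def _spec(n, rate=100.0, stride=1):
    return WindowSpec(length_ms=n * 1000.0 / rate, stride_ms=stride * 1000.0 / rate, rate=rate)


@pytest.mark.parametrize("n_win", [4, 7, 10, 16])
def test_double_loop_oracle_equivalence(rng, n_win):
    """Vectorized AR(1), tau and variance match a naive double-loop to 1e-12."""
    w = _spec(n_win)
    for _ in range(20):
        v = rng.normal(size=n_win + rng.integers(0, 30))
        ar1 = windowed_ar1(v, w)
        tau = autocorr_decay_time(v, w)
        var = windowed_variance(v, w)
        for k in range(len(ar1)):
            win = list(v[k : k + n_win])
            for got, want in (
                (ar1[k], naive_ar1(win)),
                (tau[k], naive_tau(win, w.rate)),
                (var[k], naive_var(win)),
            ):
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_alternating_window_ar1_is_minus_nine_tenths():
    v = np.array([1, -1] * 5, dtype=float)
    w = _spec(10)
    assert windowed_ar1(v, w)[0] == pytest.approx(-0.9, abs=1e-12)


def test_constant_window_yields_nan():
    w = _spec(8)
    out = windowed_ar1(np.full(8, 3.7), w)
    assert np.isnan(out[0])
    assert np.isnan(autocorr_decay_time(np.full(8, 3.7), w)[0])
    assert windowed_variance(np.full(8, 3.7), w)[0] == 0.0


def test_ar1_estimates_ar_coefficient(rng):
    """A long window over an AR(1) process recovers its coefficient."""
    phi = 0.8
    n = 4000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.normal(size=n)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + eps[k]
    w = _spec(n, rate=1000.0)
    est = windowed_ar1(x, w)[0]
    assert est == pytest.approx(phi, abs=3.0 / np.sqrt(n) + 0.01)


def test_tau_equals_ten_samples_for_ar_09(rng):
    """0.9^9 > 1/e > 0.9^10, so the decay time is 10 sample intervals."""
    phi = 0.9
    n = 20000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.normal(size=n)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + eps[k]
    rate = 1000.0
    tau = autocorr_decay_time(x, _spec(n, rate=rate))[0]
    assert tau == pytest.approx(10 * 1000.0 / rate)


def test_tau_is_one_sample_for_white_noise(rng):
    """White-noise windows decay below 1/e at the first lag, typically."""
    w = _spec(50)
    tau = autocorr_decay_time(rng.normal(size=5000), w)
    one = 1000.0 / w.rate
    frac = np.mean(tau[np.isfinite(tau)] == one)
    assert frac > 0.9


def test_two_point_variance():
    w = WindowSpec(length_ms=40, rate=100)  # 4 samples
    v = np.array([0.0, 2.0, 0.0, 2.0])
    # window variance of [0,2,0,2] is 4/3; direct two-point case via naive
    assert naive_var([0.0, 2.0]) == pytest.approx(2.0)
    assert windowed_variance(v, w)[0] == pytest.approx(4.0 / 3.0)


def test_variance_of_standard_normal(rng):
    w = _spec(5000, rate=1000.0)
    assert windowed_variance(rng.normal(size=5000), w)[0] == pytest.approx(
        1.0, abs=0.06
    )


def test_window_shorter_than_four_samples_rejected():
    with pytest.raises(ValueError):
        WindowSpec(length_ms=10, rate=240)  # 2 samples
    with pytest.raises(ValueError):
        windowed_ar1(np.arange(3.0), _spec(4))


# ---------------------------------------------------------------------------
# Detectors


def _series(ar1=None, tau=None, var=None):
    n = max(len(x) for x in (ar1, tau, var) if x is not None)
    t = np.arange(n, dtype=float)
    fill = np.full(n, np.nan)
    return EWSSeries(
        t=t,
        ar1=np.asarray(ar1, dtype=float) if ar1 is not None else fill.copy(),
        tau=np.asarray(tau, dtype=float) if tau is not None else fill.copy(),
        var=np.asarray(var, dtype=float) if var is not None else fill.copy(),
    )


def test_ar1_rise_fires_at_first_threshold_crossing():
    s = _series(ar1=[-0.2, 0.05, 0.12, 0.4])
    assert detect_ar1_rise(s, 0.1) == s.t[2]
    assert detect_ar1_rise(_series(ar1=[-0.2, 0.0, 0.09]), 0.1) is None


def test_tau_rise_requires_twenty_percent_jump():
    s = _series(tau=[5.0, 5.0, 5.0, 6.5, 6.5])
    assert detect_tau_rise(s, 0.20) == s.t[3]  # 30% jump qualifies
    s2 = _series(tau=[5.0, 5.9, 5.9, 5.9])
    assert detect_tau_rise(s2, 0.20) is None  # 18% does not


def test_tau_rise_skips_undefined_pairs():
    s = _series(tau=[5.0, np.nan, 7.0, 9.0])
    # nan breaks the (5, nan) and (nan, 7) pairs; (7, 9) is ~29%
    assert detect_tau_rise(s, 0.20) == s.t[3]


def test_var_rise_threshold():
    s = _series(var=[1e-4, 1.2e-4, 1.6e-4])
    assert detect_var_rise(s, 1.5e-4) == s.t[2]
    assert detect_var_rise(_series(var=[1e-4, 1.4e-4]), 1.5e-4) is None


# ---------------------------------------------------------------------------
# Invariance properties


@settings(max_examples=40, deadline=None)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.01, 100, allow_nan=False),
    seed=st.integers(0, 2**31 - 1),
)
def test_shift_and_scale_equivariance(shift, scale, seed):
    """AR(1) and tau ignore affine changes; variance scales quadratically."""
    r = np.random.default_rng(seed)
    v = r.normal(size=40)
    w = _spec(8)
    u = scale * v + shift
    a1, a2 = windowed_ar1(v, w), windowed_ar1(u, w)
    t1_, t2_ = autocorr_decay_time(v, w), autocorr_decay_time(u, w)
    s1, s2 = windowed_variance(v, w), windowed_variance(u, w)
    np.testing.assert_allclose(a1, a2, rtol=1e-9, atol=1e-9)
    np.testing.assert_array_equal(np.nan_to_num(t1_, nan=-1), np.nan_to_num(t2_, nan=-1))
    np.testing.assert_allclose(s2, scale**2 * s1, rtol=1e-9)


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), n_win=st.integers(4, 12))
def test_ar1_bounded(seed, n_win):
    r = np.random.default_rng(seed)
    v = r.normal(size=60)
    est = windowed_ar1(v, _spec(n_win))
    est = est[np.isfinite(est)]
    assert np.all(np.abs(est) <= 1.0 + 2.0 / n_win)


def test_window_centers_align_with_samples():
    w = _spec(4, rate=100.0)
    t = window_centers(10, w, t0=1.0)
    assert t[0] == pytest.approx(1.0 + 1.5 / 100.0)
    assert len(t) == 7
    s = compute_ews(np.random.default_rng(0).normal(size=10), w, t0=1.0)
    np.testing.assert_allclose(s.t, t)
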