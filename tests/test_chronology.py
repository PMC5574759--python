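"""Chronology construction: spline, prewhitening, biweight, EPS, crossdating."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tropichron import (
    RingSeries,
    biweight_mean,
    build_chronology,
    crossdate_check,
    detrend,
    eps,
    fit_spline_growth,
    lag1_autocorrelation,
    mean_interseries_correlation,
    prewhiten,
    running_eps,
)
from tropichron.chronology import critical_r
from tropichron.errors import (
    DomainError,
    EmptyChronologyError,
    SeriesTooShortError,
    UndefinedStatisticError,
)
from tropichron.types import Chronology, DetrendedSeries

from conftest import fft_amplitude


def _sinusoid_series(period, n=300, mean=5.0, amp=1.0):
    t = np.arange(n)
    return RingSeries("SIN", 1700, mean + amp * np.sin(2 * np.pi * t / period))


# ---------------------------------------------------------------------------
# fit_spline_growth / detrend

def test_spline_constant_series_is_interpolated_exactly():
    s = RingSeries("C", 1900, np.full(80, 5.0))
    curve = fit_spline_growth(s)
    assert np.allclose(curve, 5.0, atol=1e-8)


def test_spline_transfer_at_60yr_is_half():
    s = _sinusoid_series(60)
    curve = fit_spline_growth(s, wavelength=60, response=0.5)
    transfer = fft_amplitude(curve, 60) / fft_amplitude(s.widths, 60)
    assert 0.45 <= transfer <= 0.55


def test_spline_passes_high_frequency_to_index():
    s = _sinusoid_series(10)
    curve = fit_spline_growth(s, wavelength=60, response=0.5)
    assert fft_amplitude(curve, 10) < 0.1


def test_spline_guards():
    with pytest.raises(SeriesTooShortError):
        fit_spline_growth(RingSeries("S", 1900, np.ones(5)))
    with pytest.raises(DomainError):
        fit_spline_growth(RingSeries("S", 1900, np.zeros(20)))


def test_detrend_identity_and_ratio():
    s = RingSeries("D", 1900, np.linspace(1, 2, 50))
    d = detrend(s, s.widths.copy())
    assert np.allclose(d.index, 1.0)
    curve = s.widths / np.where(np.arange(50) == 10, 2.0, 1.0)
    d2 = detrend(s, curve)
    assert d2.index[10] == pytest.approx(2.0)
    assert np.allclose(np.delete(d2.index, 10), 1.0)


def test_detrend_geometric_mean_index_matches_lognormal_oracle():
    # 1000 lognormal series detrended by their own fitted curve.  The
    # least-squares curve tracks the arithmetic local mean, so the
    # geometric mean of the ratio index carries the lognormal bias
    # E[exp(Z)]/exp(E[Z]) = exp(sigma^2/2) in the denominator: the
    # oracle value is exp(-sigma^2/2), not 1.  We check the mean of the
    # statistic against that closed form within 2 SD of its own spread,
    # and separately that the arithmetic-mean index is unbiased near 1.
    rng = np.random.default_rng(77)
    sigma = 0.2
    gms, ams = [], []
    for _ in range(1000):
        w = np.exp(rng.normal(0.5, sigma, 60))
        s = RingSeries("G", 1900, w)
        d = detrend(s, fit_spline_growth(s))
        gms.append(np.exp(np.mean(np.log(d.index))))
        ams.append(np.mean(d.index))
    oracle = np.exp(-sigma ** 2 / 2.0)
    assert abs(np.mean(gms) - oracle) <= 2 * np.std(gms, ddof=1)
    assert abs(np.mean(ams) - 1.0) <= 2 * np.std(ams, ddof=1)


# ---------------------------------------------------------------------------
# prewhiten

def test_prewhiten_white_noise_selects_order_zero():
    # AIC is known to overfit: the asymptotic chance of adding a
    # spurious AR term is about 15.7% per order, so order 0 is picked
    # for white noise only ~70% of the time.  60% is ~3 binomial SE
    # below that theoretical rate.
    rng = np.random.default_rng(8)
    hits = 0
    for _ in range(200):
        d = DetrendedSeries("W", np.arange(1900, 2000),
                            1.0 + rng.normal(0, 0.1, 100))
        hits += prewhiten(d, max_order=5).ar_order == 0
    assert hits >= 120


def test_prewhiten_ar1_removes_autocorrelation():
    rng = np.random.default_rng(9)
    x = np.empty(300)
    x[0] = rng.normal()
    for t in range(1, 300):
        x[t] = 0.7 * x[t - 1] + rng.normal()
    d = DetrendedSeries("A", np.arange(1700, 2000), 1.0 + 0.1 * x)
    out = prewhiten(d, max_order=5)
    assert out.ar_order >= 1
    v = out.index[np.isfinite(out.index)]
    lag1 = np.corrcoef(v[:-1], v[1:])[0, 1]
    assert -0.1 <= lag1 <= 0.1
    # re-centering contract: mean preserved
    assert np.mean(v) == pytest.approx(np.mean(d.index), abs=0.05)


def test_prewhiten_too_short_rejected():
    d = DetrendedSeries("S", np.arange(10), np.ones(10))
    with pytest.raises(SeriesTooShortError):
        prewhiten(d, max_order=5)


# ---------------------------------------------------------------------------
# biweight mean / build_chronology

def test_biweight_equals_mean_for_equal_inputs():
    assert biweight_mean([2.5] * 6) == pytest.approx(2.5)


def test_biweight_downweights_outlier():
    vals = [1, 1, 1, 1, 100]
    b = biweight_mean(vals)
    assert b < np.mean(vals)
    assert 0.9 <= b <= 1.2


def _biweight_oracle(v, c=9.0):
    """Independent direct iteration of the biweight formula."""
    v = np.asarray(v, dtype=float)
    m = np.median(v)
    for _ in range(200):
        s = np.median(np.abs(v - m))
        if s == 0:
            return m
        u = (v - m) / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        m_new = np.sum(w * v) / np.sum(w)
        if abs(m_new - m) < 1e-10:
            return m_new
        m = m_new
    return m


def test_biweight_matches_direct_iteration_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        v = rng.normal(1.0, 0.4, size=rng.integers(5, 30))
        assert biweight_mean(v) == pytest.approx(_biweight_oracle(v), abs=1e-6)


@given(st.lists(st.floats(min_value=-100, max_value=100,
                          allow_nan=False), min_size=1, max_size=40))
def test_biweight_within_input_range(vals):
    b = biweight_mean(vals)
    assert min(vals) - 1e-9 <= b <= max(vals) + 1e-9


def test_build_chronology_degenerate_agreement():
    years = np.arange(1900, 1960)
    rng = np.random.default_rng(3)
    idx = 1.0 + rng.normal(0, 0.2, 60)
    series = [DetrendedSeries(f"S{i}", years, idx.copy()) for i in range(3)]
    chron = build_chronology(series)
    assert np.allclose(chron.index, idx, atol=1e-8)
    assert np.all(chron.depth == 3)


def test_build_chronology_empty_overlap_rejected():
    a = DetrendedSeries("A", np.array([1900]), np.array([1.0]))
    b = DetrendedSeries("B", np.array([1950]), np.array([1.0]))
    with pytest.raises(EmptyChronologyError):
        build_chronology([a, b], min_depth=2)


# ---------------------------------------------------------------------------
# r-bar and EPS

def test_rbar_identical_series_is_one():
    years = np.arange(1900, 1950)
    rng = np.random.default_rng(2)
    idx = 1.0 + rng.normal(0, 0.2, 50)
    series = [DetrendedSeries(f"S{i}", years, idx.copy()) for i in range(3)]
    assert mean_interseries_correlation(series) == pytest.approx(1.0)


def test_rbar_antiphase_sinusoids_is_minus_one():
    years = np.arange(1900, 1960)
    t = np.arange(60)
    a = DetrendedSeries("A", years, np.sin(2 * np.pi * t / 12))
    b = DetrendedSeries("B", years, -np.sin(2 * np.pi * t / 12))
    assert mean_interseries_correlation([a, b]) == pytest.approx(-1.0)


def test_rbar_independent_noise_near_zero():
    rng = np.random.default_rng(11)
    years = np.arange(1800, 2000)
    series = [DetrendedSeries(f"S{i}", years, rng.normal(1, 0.1, 200))
              for i in range(7)]  # 21 pairs
    rbar = mean_interseries_correlation(series)
    # SE of one pairwise r at n=200 is ~1/sqrt(200); under the null the
    # 21 pairwise correlations are uncorrelated.
    se = (1 / np.sqrt(200)) / np.sqrt(21)
    assert abs(rbar) <= 2 * se


def test_rbar_no_qualifying_pair_rejected():
    a = DetrendedSeries("A", np.arange(1900, 1910), np.ones(10))
    b = DetrendedSeries("B", np.arange(1900, 1910), np.ones(10))
    with pytest.raises(UndefinedStatisticError):
        mean_interseries_correlation([a, b], min_overlap=20)


def test_eps_closed_form_limits():
    assert eps(1.0, 7) == pytest.approx(1.0)
    assert eps(0.0, 7) == pytest.approx(0.0)
    with pytest.raises(DomainError):
        eps(1.5, 7)
    with pytest.warns(UserWarning):
        assert eps(-0.2, 7) == 0.0


def test_eps_monotone_in_rbar_and_n():
    grid = np.linspace(0.05, 0.95, 10)
    for n in (2, 5, 15, 40):
        vals = [eps(r, n) for r in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
    for r in (0.1, 0.49, 0.8):
        vals = [eps(r, n) for n in (2, 5, 15, 40)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# running EPS

def _onset_test_set(seed=21):
    """Eight series sharing a strong signal only from 1950 on."""
    rng = np.random.default_rng(seed)
    years = np.arange(1900, 2001)
    signal = rng.normal(0, 0.3, len(years))
    signal[years < 1950] = 0.0
    return [
        DetrendedSeries(f"T{i:02d}A", years,
                        1.0 + signal + rng.normal(0, 0.1, len(years)))
        for i in range(8)
    ]


def test_running_eps_onset_detected_within_one_step():
    windows, onset = running_eps(_onset_test_set(), window=50, step=25)
    assert onset is not None
    assert abs(onset - 1950) <= 25


def test_running_eps_identical_series_all_one():
    years = np.arange(1900, 2001)
    rng = np.random.default_rng(6)
    idx = 1.0 + rng.normal(0, 0.2, len(years))
    series = [DetrendedSeries(f"T{i:02d}A", years, idx.copy())
              for i in range(4)]
    windows, onset = running_eps(series)
    assert windows
    assert all(w.eps == pytest.approx(1.0) for w in windows)
    assert onset == windows[0].start


def test_running_eps_impossible_threshold_never_passes():
    windows, onset = running_eps(_onset_test_set(), threshold=1.01)
    assert onset is None


def test_running_eps_window_guard():
    with pytest.raises(DomainError):
        running_eps(_onset_test_set(), window=20)


# ---------------------------------------------------------------------------
# crossdating

def _crossdate_set(seed, n_series=6, n_years=100, noise=0.3):
    rng = np.random.default_rng(seed)
    years = np.arange(1900, 1900 + n_years)
    signal = rng.normal(0, 1, n_years)
    series = [
        DetrendedSeries(f"T{i:02d}A", years.copy(),
                        1.0 + signal + rng.normal(0, noise, n_years))
        for i in range(n_series)
    ]
    return years, series


def test_crossdate_series_equal_to_master_passes():
    _, series = _crossdate_set(seed=31, noise=0.05)
    report = crossdate_check(series[0], series[1:])
    assert report.segments
    assert all(s.passed for s in report.segments)
    assert all(s.best_lag == 0 for s in report.segments)


def test_crossdate_shifted_series_fails_with_lag_minus_one():
    years, series = _crossdate_set(seed=32, noise=0.2)
    shifted = DetrendedSeries("T00A", series[0].years + 1, series[0].index)
    report = crossdate_check(shifted, series[1:])
    full = [s for s in report.segments if not s.partial]
    assert sum(not s.passed for s in full) > len(full) / 2
    lags = [s.best_lag for s in full]
    assert max(set(lags), key=lags.count) == -1


def test_crossdate_null_failure_rate_matches_design_rate():
    # A 20-year white-noise segment against an unrelated master fails
    # (r < one-tailed 99% critical value) with probability 0.99 exactly.
    rng = np.random.default_rng(33)
    years = np.arange(1980, 2000)
    fails = 0
    n_trials = 500
    for _ in range(n_trials):
        a = DetrendedSeries("A01X", years, rng.normal(1, 0.1, 20))
        others = [DetrendedSeries(f"B{i:02d}X", years, rng.normal(1, 0.1, 20))
                  for i in range(2)]
        rep = crossdate_check(a, others, seg_len=20, seg_step=10)
        assert len(rep.segments) == 1
        fails += not rep.segments[0].passed
    rate = fails / n_trials
    se = np.sqrt(0.99 * 0.01 / n_trials)
    assert abs(rate - 0.99) <= 3 * se


def test_crossdate_short_overlap_gives_no_segments():
    years = np.arange(1990, 2000)
    a = DetrendedSeries("A01X", years, np.random.default_rng(1).normal(1, 0.1, 10))
    b = DetrendedSeries("B01X", years, np.random.default_rng(2).normal(1, 0.1, 10))
    rep = crossdate_check(a, [b], seg_len=20)
    assert rep.segments == []


def test_critical_r_matches_t_distribution():
    # Independent oracle: invert the exact null relation
    # t = r sqrt(n-2) / sqrt(1 - r^2) at the one-tailed 99% point.
    from scipy import stats

    n = 20
    t = stats.t.ppf(0.99, n - 2)
    expected = t / np.sqrt(t ** 2 + n - 2)
    assert critical_r(20, 0.01) == pytest.approx(expected, abs=1e-12)
    assert 0.51 <= critical_r(20, 0.01) <= 0.53


# ---------------------------------------------------------------------------
# lag-1 autocorrelation

def _chron(values):
    values = np.asarray(values, dtype=float)
    years = np.arange(1900, 1900 + len(values))
    return Chronology(years, values, np.full(len(values), 2))


def test_lag1_alternating_is_minus_one():
    assert lag1_autocorrelation(_chron([1, -1] * 15)) == pytest.approx(-1.0)


def test_lag1_constant_undefined():
    with pytest.raises(UndefinedStatisticError):
        lag1_autocorrelation(_chron(np.ones(30)))


def test_lag1_short_series_undefined():
    with pytest.raises(UndefinedStatisticError):
        lag1_autocorrelation(_chron(np.arange(10)))


def test_lag1_ar1_simulation_oracle():
    rng = np.random.default_rng(14)
    x = np.empty(2000)
    x[0] = rng.normal()
    for t in range(1, 2000):
        x[t] = -0.2 * x[t - 1] + rng.normal()
    r = lag1_autocorrelation(_chron(x))
    assert -0.25 <= r <= -0.15
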