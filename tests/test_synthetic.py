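"""Synthetic-data generator: limits, determinism, and statistical oracles."""

import numpy as np
import pytest

from tropichron import (
    SimConfig,
    gen_14c_measurements,
    gen_bomb_curve,
    gen_climate,
    gen_gridded_field,
    gen_ring_series,
    ond_signal,
)
from tropichron.errors import ConfigError, SelectionError
from tropichron.synthetic import (
    _FLOW_CYCLE,
    _PRECIP_CYCLE,
    _TEMP_CYCLE,
    FLAG_EXTRA,
    FLAG_MERGED,
    RingRecord,
    TruthTable,
    default_sample_positions,
)

ZERO_COUPLINGS = {"precip": 0.0, "temp": 0.0, "streamflow": 0.0, "level": 0.0}


# ---------------------------------------------------------------------------
# gen_climate

def test_climate_noise_free_limit_equals_seasonal_cycles():
    cfg = SimConfig(span=(1950, 2000), seed=3)
    series, _ = gen_climate(cfg, couplings=ZERO_COUPLINGS, noise_scale=0.0)
    for name, cycle in [("precip", _PRECIP_CYCLE), ("temp", _TEMP_CYCLE),
                        ("streamflow", _FLOW_CYCLE)]:
        monthly = series[name].monthly
        assert np.allclose(monthly, cycle[None, :], atol=1e-12), name


def test_climate_determinism_same_seed_bit_identical():
    cfg = SimConfig(seed=42)
    s1, i1 = gen_climate(cfg)
    s2, i2 = gen_climate(cfg)
    for name in s1:
        assert np.array_equal(s1[name].monthly, s2[name].monthly)
    for name in i1:
        assert np.array_equal(i1[name].values, i2[name].values)


def test_climate_streamflow_index_coupling_vs_monte_carlo_oracle():
    # Independent brute-force oracle: simulate the documented model for
    # 10^4 years and measure corr(annual-mean flow, z) directly.
    phi, coupling, sd = 0.5, -0.6, 0.25
    rng = np.random.default_rng(987654)
    n = 10_000
    z = np.empty(n)
    z[0] = rng.normal()
    innov = rng.normal(0, np.sqrt(1 - phi ** 2), n)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov[t]
    flow = _FLOW_CYCLE[None, :] * np.exp(
        coupling * z[:, None] + rng.normal(0, sd, (n, 12)))
    oracle = np.corrcoef(flow.mean(axis=1), z)[0, 1]

    rs = []
    for seed in range(20):
        cfg = SimConfig(span=(1801, 2000), seed=seed)
        series, indices = gen_climate(cfg)
        annual = series["streamflow"].monthly.mean(axis=1)
        rs.append(np.corrcoef(annual, indices["oni"].values)[0, 1])
    assert abs(np.mean(rs) - oracle) < 0.1


def test_climate_too_short_span_rejected():
    with pytest.raises(ConfigError):
        gen_climate(SimConfig(span=(1990, 2000)))  # < 40 years


# ---------------------------------------------------------------------------
# gen_ring_series

def _clean_config(**kw):
    base = dict(p_extra=0.0, p_merge=0.0, p_missing=0.0, recruit_span=0)
    base.update(kw)
    return SimConfig(**base)


def test_ring_series_no_error_limit_recovers_true_years():
    cfg = _clean_config(n_trees=4, span=(1900, 2000), seed=5)
    clim, _ = gen_climate(cfg)
    series, truth = gen_ring_series(cfg, clim["streamflow"])
    span_len = cfg.span[1] - cfg.span[0] + 1
    for s in series:
        assert len(s.widths) == span_len
    for tid, recs in truth.rings.items():
        for pos in range(len(recs)):
            assert truth.dendro_year(tid, pos) == truth.true_year(tid, pos)


def test_ring_series_extra_ring_binomial_expectation():
    # Event years are drawn at the population level; with participation 1
    # the per-tree extra count per seed is one Binomial(span, p) draw, so
    # the oracle averages over seeds and uses the SE of that mean.
    p, span_years, n_seeds = 0.1, 100, 20
    counts = []
    for seed in range(n_seeds):
        cfg = _clean_config(n_trees=1, span=(1901, 2000), p_extra=p,
                            extra_era=None, seed=seed)
        clim, _ = gen_climate(cfg)
        _, truth = gen_ring_series(cfg, clim["streamflow"])
        counts.append(truth.n_extra("PG01"))
    expected = span_years * p
    se = np.sqrt(span_years * p * (1 - p) / n_seeds)
    assert abs(np.mean(counts) - expected) <= 2 * se


def test_ring_series_deterministic_age_trend_limit():
    cfg = _clean_config(n_trees=2, span=(1900, 2000), beta=0.0,
                        sigma_ring=0.0, seed=1)
    clim, _ = gen_climate(cfg)
    series, _ = gen_ring_series(cfg, clim["streamflow"])
    A, k, c = cfg.age_trend
    ages = np.arange(len(series[0].widths))
    expected = A * np.exp(-k * ages) + c
    for s in series:
        assert np.allclose(s.widths, expected, rtol=1e-10)


def test_ring_series_truth_invariants():
    cfg = SimConfig(n_trees=6, p_extra=0.3, p_merge=0.0, seed=2)
    clim, _ = gen_climate(cfg)
    _, truth = gen_ring_series(cfg, clim["streamflow"])
    for tid, recs in truth.rings.items():
        years = [r.true_year for r in recs]
        assert all(a <= b for a, b in zip(years, years[1:]))
        n_extra = sum(r.flag == FLAG_EXTRA for r in recs)
        assert n_extra == len(recs) - len(set(years))
        for r in recs:
            if r.flag == FLAG_EXTRA:
                assert recs[r.position - 1].true_year == r.true_year


def test_ring_series_determinism():
    cfg = SimConfig(n_trees=3, seed=9)
    clim, _ = gen_climate(cfg)
    s1, t1 = gen_ring_series(cfg, clim["streamflow"])
    s2, t2 = gen_ring_series(cfg, clim["streamflow"])
    for a, b in zip(s1, s2):
        assert a.series_id == b.series_id
        assert np.array_equal(a.widths, b.widths)
    assert t1.to_dict() == t2.to_dict()


def test_ring_series_climate_span_mismatch_rejected():
    cfg = SimConfig(span=(1830, 2006))
    clim, _ = gen_climate(SimConfig(span=(1900, 2006)))
    with pytest.raises(ConfigError):
        gen_ring_series(cfg, clim["streamflow"])


def test_config_validation_guards():
    with pytest.raises(ConfigError):
        SimConfig(p_extra=1.2).validate()
    with pytest.raises(ConfigError):
        SimConfig(p_extra=0.6, p_merge=0.5).validate()
    with pytest.raises(ConfigError):
        SimConfig(age_trend=(-1.0, 0.02, 0.5)).validate()
    with pytest.raises(ConfigError):
        SimConfig(meas_sd_fm=0.0).validate()
    with pytest.raises(ConfigError):
        SimConfig(participation=1.5).validate()


# ---------------------------------------------------------------------------
# gen_bomb_curve

def test_bomb_curve_single_global_maximum(curve):
    peak = curve.fm.max()
    assert int(np.sum(curve.fm == peak)) == 1


def test_bomb_curve_monotone_limbs(curve):
    fm = curve.fm
    years = curve.years
    ipk = int(np.argmax(fm))
    rise = fm[(years >= 1954) & (years <= years[ipk])]
    assert np.all(np.diff(rise) > 0)
    decay = fm[ipk:]
    assert np.all(np.diff(decay) < 0)


def test_bomb_curve_two_limb_crossings(curve):
    # Exhaustive scan: any level strictly between the end-of-record value
    # and the peak must cross the curve exactly twice (once per limb).
    fm = curve.fm
    lo, hi = fm[-1], fm.max()
    for level in np.linspace(lo + 1e-4, hi - 1e-4, 200):
        crossings = np.sum(np.diff(np.sign(fm - level)) != 0)
        assert crossings == 2, f"level {level}: {crossings} crossings"


# ---------------------------------------------------------------------------
# gen_14c_measurements

def _truth_and_curve(seed=7, **kw):
    cfg = SimConfig(seed=seed, **kw)
    clim, _ = gen_climate(cfg)
    _, truth = gen_ring_series(cfg, clim["streamflow"])
    return cfg, truth, gen_bomb_curve()


def test_c14_noise_free_limit_equals_curve_value():
    cfg, truth, curve = _truth_and_curve(meas_sd_fm=1e-12, n_trees=3)
    samples = gen_14c_measurements(truth, curve, cfg, tree_ids=["PG01"])
    for s in samples:
        assert s.fm == pytest.approx(float(curve.fm_at(s.true_year)), abs=1e-9)


def test_c14_extra_ring_shares_expected_fm_with_predecessor():
    cfg, truth, curve = _truth_and_curve(meas_sd_fm=1e-12, n_trees=3,
                                         p_extra=0.4)
    recs = truth.rings["PG01"]
    extras = [r for r in recs if r.flag == FLAG_EXTRA]
    assert extras, "construction should produce extra rings"
    pos = extras[0].position
    samples = gen_14c_measurements(
        truth, curve, cfg, positions={"PG01": [pos - 1, pos]})
    assert samples[0].fm == pytest.approx(samples[1].fm, abs=1e-9)


def test_c14_default_positions_selection_rule():
    # 8 samples spaced 10 apart on a 90-ring tree span positions 1..71.
    truth = TruthTable(harvest_year=2006)
    truth.rings["T1"] = [RingRecord(i, 1917 + i, "annual") for i in range(90)]
    positions = default_sample_positions(truth, "T1", n_samples=8, spacing=10,
                                         target_last_dendro=2006 - 18)
    assert positions == [1, 11, 21, 31, 41, 51, 61, 71]


def test_c14_position_beyond_ring_count_rejected():
    cfg, truth, curve = _truth_and_curve(n_trees=2)
    n = truth.n_rings("PG01")
    with pytest.raises(SelectionError):
        gen_14c_measurements(truth, curve, cfg, positions={"PG01": [n + 5]})


def test_c14_determinism():
    cfg, truth, curve = _truth_and_curve(n_trees=3)
    s1 = gen_14c_measurements(truth, curve, cfg, tree_ids=["PG01", "PG02"])
    s2 = gen_14c_measurements(truth, curve, cfg, tree_ids=["PG01", "PG02"])
    assert [(a.tree_id, a.dendro_year, a.fm) for a in s1] == \
           [(a.tree_id, a.dendro_year, a.fm) for a in s2]


# ---------------------------------------------------------------------------
# gen_gridded_field / ond_signal

def test_gridded_field_shapes_and_coordinates():
    cfg = SimConfig(span=(1950, 2000), seed=1)
    _, indices = gen_climate(cfg)
    g = gen_gridded_field(cfg, indices["oni"], n_lat=6, n_lon=7)
    assert g.values.shape == (6, 7, len(indices["oni"].years))
    assert np.all(np.diff(g.lat) > 0) and np.all(np.diff(g.lon) > 0)


def test_ond_signal_is_standardized():
    cfg = SimConfig(seed=4)
    clim, _ = gen_climate(cfg)
    sig = ond_signal(clim["streamflow"])
    assert abs(np.nanmean(sig.values)) < 1e-10
    assert np.nanstd(sig.values) == pytest.approx(1.0, abs=1e-10)
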