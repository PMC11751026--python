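"""Loess smoothing, span CV, detrending, peak detection, KL divergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cupmix.synthetic import SyntheticConfig, default_compounds, generate_campaign
from cupmix.temporal import (
    MonthlySeries,
    ProbabilityCurve,
    compare_systems,
    detect_peaks,
    detrend_linear,
    fit_loess,
    kl_divergence,
    monthly_series,
    select_span_cv,
    to_probability,
)

GRID = np.arange(13.0)


def series(values):
    return MonthlySeries(np.arange(float(len(values))), np.asarray(values, float))


@pytest.mark.parametrize("span", [0.3, 0.5, 1.0])
@pytest.mark.parametrize("degree", [1, 2])
def test_loess_reproduces_linear(span, degree):
    s = series(2.0 * GRID + 1.0)
    fit = fit_loess(s, span, degree)
    assert fit.fitted == pytest.approx(s.values, abs=1e-8)


def test_loess_constant_stays_constant():
    fit = fit_loess(series(np.full(13, 3.5)), 0.5)
    assert fit.fitted == pytest.approx(np.full(13, 3.5), abs=1e-10)


def test_loess_smooths_noisy_sinusoid():
    rng = np.random.default_rng(11)
    true = np.sin(2 * np.pi * GRID / 12.0)
    noisy = true + rng.normal(0, 0.3, 13)
    fit = fit_loess(series(noisy), 0.6)
    assert np.mean((fit.fitted - true) ** 2) < np.mean((noisy - true) ** 2)


def test_degree1_loess_matches_statsmodels_lowess():
    """Independent oracle: the locally linear path agrees with statsmodels."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(4)
    y = np.cos(GRID / 2.0) + rng.normal(0, 0.2, 13)
    span = 7 / 13  # same 7-point window in both implementations
    ours = fit_loess(series(y), span, degree=1).fitted
    theirs = sm.nonparametric.lowess(y, GRID, frac=span, it=0,
                                     return_sorted=False)
    assert ours == pytest.approx(theirs, abs=1e-8)


def test_span_cv_prefers_largest_on_linear():
    s = series(2.0 * GRID + 1.0)
    assert select_span_cv(s, [0.4, 0.6, 1.0]) == 1.0


def test_span_cv_skips_infeasible_candidates():
    s = series(2.0 * GRID + 1.0)
    assert select_span_cv(s, [0.05, 1.0]) == 1.0
    with pytest.raises(ValueError):
        select_span_cv(s, [0.01, 0.05])


def test_span_cv_tracks_planted_smoothness():
    """On a smooth signal + noise, the CV-selected span beats the grid
    extremes on an independent noisy replicate."""
    rng = np.random.default_rng(7)
    true = 3.0 + 2.0 * np.sin(2 * np.pi * GRID / 12.0)
    train = true + rng.normal(0, 0.4, 13)
    test = true + rng.normal(0, 0.4, 13)
    grid = [0.3, 0.5, 0.7, 1.0]
    chosen = select_span_cv(series(train), grid)

    def test_mse(span):
        return np.mean((fit_loess(series(train), span).fitted - test) ** 2)

    assert test_mse(chosen) <= min(test_mse(grid[0]), test_mse(grid[-1])) + 1e-9


def test_detrend_removes_exact_line():
    res = detrend_linear(series(2.0 * GRID + 1.0))
    assert res.values == pytest.approx(np.zeros(13), abs=1e-10)


def test_detrend_residuals_sum_to_zero():
    rng = np.random.default_rng(3)
    res = detrend_linear(series(rng.normal(5, 2, 13)))
    assert abs(res.values.sum()) < 1e-9


def test_detrend_flags_outlier():
    vals = np.array([1.0, 2.0, 3.0, 10.0, 5.0])
    res = detrend_linear(series(vals))
    assert np.argmax(np.abs(res.values)) == 3


def test_peak_simple_triangle():
    ps = detect_peaks([0.0, 1.0, 0.0], delta=0.3)
    assert [(p.position, p.value, p.kind) for p in ps.peaks] == [
        (1, 1.0, "maximum")]


def test_peak_hand_trace_with_shoulder():
    """The 0.8 dip is within delta of the running max, so the detector keeps
    climbing and emits the maximum at the 1.7 summit; the trailing minimum
    stays pending."""
    ps = detect_peaks([0.0, 1.0, 0.8, 1.7, 0.2], delta=0.3)
    assert [(p.position, p.value, p.kind) for p in ps.peaks] == [
        (3, 1.7, "maximum")]


def test_peak_constant_sequence_none():
    assert detect_peaks(np.full(10, 2.0), delta=0.3).peaks == ()


def test_peak_alternating_kinds():
    vals = [0, 2, 0, 2, 0, 2, 0]
    kinds = [p.kind for p in detect_peaks(vals, 0.5).peaks]
    assert len(kinds) == 5  # three summits, two confirmed valleys
    assert kinds[0] == "maximum"
    assert all(a != b for a, b in zip(kinds, kinds[1:]))


@given(shift=st.floats(-50, 50, allow_nan=False))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_peak_positions_shift_invariant(shift):
    vals = np.array([0.0, 1.0, 0.2, 1.5, 0.1, 0.6, 0.0])
    base = detect_peaks(vals, 0.3)
    moved = detect_peaks(vals + shift, 0.3)
    assert [p.position for p in base.peaks] == [p.position for p in moved.peaks]


def test_to_probability_normalises():
    from cupmix.temporal import SmoothedSeries
    sm = SmoothedSeries(np.arange(3.0), np.array([1.0, 1.0, 2.0]), span=0.5)
    p = to_probability(sm)
    assert p.p == pytest.approx([0.25, 0.25, 0.5])


def test_to_probability_floors_negative_values():
    from cupmix.temporal import SmoothedSeries
    sm = SmoothedSeries(np.arange(3.0), np.array([1.0, -0.01, 2.0]), span=0.5)
    p = to_probability(sm, epsilon=1e-6)
    assert p.p[1] == pytest.approx(1e-6 / (3.0 + 1e-6))
    with pytest.raises(ValueError):
        to_probability(SmoothedSeries(np.arange(3.0), np.array([-1.0, -2.0, 0.0]),
                                      span=0.5))


@given(st.lists(st.floats(0.01, 100), min_size=5, max_size=5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_probability_sums_to_one(values):
    from cupmix.temporal import SmoothedSeries
    sm = SmoothedSeries(np.arange(5.0), np.asarray(values), span=0.5)
    assert to_probability(sm).p.sum() == pytest.approx(1.0, abs=1e-12)


def test_kl_identity_is_zero():
    p = ProbabilityCurve(np.arange(2.0), np.array([0.5, 0.5]))
    assert kl_divergence(p, p) == 0.0


def test_kl_hand_value():
    p = ProbabilityCurve(np.arange(2.0), np.array([0.5, 0.5]))
    q = ProbabilityCurve(np.arange(2.0), np.array([0.25, 0.75]))
    assert kl_divergence(p, q) == pytest.approx(0.2075, abs=1e-4)


def test_kl_grid_mismatch_errors():
    p = ProbabilityCurve(np.arange(2.0), np.array([0.5, 0.5]))
    q = ProbabilityCurve(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError):
        kl_divergence(p, q)


def test_kl_nonnegative_on_random_pairs():
    rng = np.random.default_rng(12)
    grid = np.arange(13.0)
    for _ in range(1000):
        a = rng.dirichlet(np.ones(13))
        b = rng.dirichlet(np.ones(13))
        a = np.maximum(a, 1e-9); a /= a.sum()
        b = np.maximum(b, 1e-9); b /= b.sum()
        kl = kl_divergence(ProbabilityCurve(grid, a), ProbabilityCurve(grid, b))
        assert kl >= -1e-12


def test_compare_identical_series_all_zero():
    s = series(np.sin(GRID) + 2.0)
    mat = compare_systems({"a": s, "b": s}, span=0.6)
    assert np.allclose(mat.to_numpy(), 0.0)
    assert np.all(np.diag(mat.to_numpy()) == 0.0)


def test_identical_calendars_give_near_zero_kl():
    """Noise off + the same calendar in every system -> indistinguishable
    annual courses."""
    base = default_compounds()[:6]
    shared = {s: (2, 4) for s in ("arable", "vegetable", "viticulture")}
    comps = tuple(type(c)(c.compound_id, c.pclass, c.dose_ug_kg,
                          c.dt50_months, c.loq_ug_kg, c.lod_ug_kg, shared)
                  for c in base)
    cfg = SyntheticConfig(seed=0, compounds=comps, noise_cv=0.0)
    table, _ = generate_campaign(cfg)
    ser = {s: monthly_series(table, "soil", s)
           for s in ("arable", "vegetable", "viticulture")}
    mat = compare_systems(ser, span=0.6)
    assert (mat.to_numpy() < 1e-6).all()


def test_monthly_series_pools_replicates(campaign):
    table, _ = campaign
    ms = monthly_series(table, "soil", "arable")
    assert len(ms.grid) == 13
    assert np.all(np.isfinite(ms.values))
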