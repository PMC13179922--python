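"""Product-limit, truncation-CDF and residual-censoring estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ltrcks as lk
from ltrcks.estimators import CDF_TOL


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def test_validate_sample_accepts_consistent_input():
    s = lk.validate_sample([0, 1, 0], [2, 3, 4], [1, 1, 0], "A")
    assert s.n == 3 and s.label == "A"
    np.testing.assert_array_equal(s.status, [1, 1, 0])


@pytest.mark.parametrize(
    "entry,time,status,err",
    [
        ([5], [2], [1], lk.EntryExceedsTimeError),
        ([0, 0], [1, 2], [0, 0], lk.NoEventsError),
        ([0, 1], [1], [1], lk.LengthMismatchError),
        ([0, np.nan], [1, 2], [1, 1], lk.NonFiniteError),
        ([0, 0], [1, 2], [1, 2], lk.InvalidStatusError),
    ],
)
def test_validate_sample_rejects_each_violation_distinctly(entry, time, status, err):
    with pytest.raises(err):
        lk.validate_sample(entry, time, status, "A")


def test_record_with_entry_equal_to_time_is_accepted():
    # the inclusive risk-set convention admits U = Y records
    s = lk.validate_sample([2, 0], [2, 3], [1, 1], "A")
    assert s.n == 2


# ---------------------------------------------------------------------------
# risk table
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "records,times,deaths,at_risk",
    [
        ([(0, 2, 1), (1, 3, 1), (0, 4, 0)], [2, 3], [1, 1], [3, 2]),
        ([(0, 1, 1)], [1], [1], [1]),
        # tie at 2; the record entering exactly at 2 counts as at risk
        ([(0, 2, 1), (0, 2, 1), (2, 5, 0)], [2], [2], [3]),
    ],
)
def test_risk_table_inclusive_convention(records, times, deaths, at_risk):
    e, t, d = zip(*records)
    rt = lk.build_risk_table(lk.validate_sample(e, t, d, "A"))
    np.testing.assert_array_equal(rt.event_times, times)
    np.testing.assert_array_equal(rt.deaths, deaths)
    np.testing.assert_array_equal(rt.at_risk, at_risk)


@settings(derandomize=True, max_examples=25)
@given(st.randoms(use_true_random=False))
def test_risk_table_invariant_under_record_permutation(r):
    rng = np.random.default_rng(r.randrange(2**32))
    n = rng.integers(3, 30)
    entry = rng.uniform(0, 2, n)
    time = entry + rng.exponential(1.0, n)
    status = rng.integers(0, 2, n)
    status[rng.integers(0, n)] = 1
    s1 = lk.validate_sample(entry, time, status, "A")
    perm = rng.permutation(n)
    s2 = lk.validate_sample(entry[perm], time[perm], status[perm], "A")
    r1, r2 = lk.build_risk_table(s1), lk.build_risk_table(s2)
    np.testing.assert_array_equal(r1.event_times, r2.event_times)
    np.testing.assert_array_equal(r1.deaths, r2.deaths)
    np.testing.assert_array_equal(r1.at_risk, r2.at_risk)


# ---------------------------------------------------------------------------
# product-limit estimator
# ---------------------------------------------------------------------------


def test_product_limit_worked_example(toy_sample):
    f = lk.fit_ltrc_cdf(toy_sample, hole_correction=False)
    np.testing.assert_allclose(f.cdf([2, 3]), [1 / 3, 2 / 3], atol=1e-15)
    assert f.total_mass == pytest.approx(2 / 3)
    fc = lk.fit_ltrc_cdf(toy_sample, hole_correction=True)
    np.testing.assert_allclose(fc.cdf([2, 3]), [1 / 4, 1 / 2], atol=1e-15)


def test_reduces_to_empirical_cdf_without_truncation_or_censoring():
    s = lk.validate_sample([-1, -1, -1], [1, 2, 3], [1, 1, 1], "A")
    f = lk.fit_ltrc_cdf(s, hole_correction=False)
    np.testing.assert_allclose(f.mass, [1 / 3, 1 / 3, 1 / 3], atol=1e-15)
    assert f.total_mass == pytest.approx(1.0)


def test_matches_kaplan_meier_oracle_without_truncation():
    """Entry below every observed time disables truncation: the fit must
    coincide with an independent Kaplan-Meier implementation at every atom."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    time = np.round(rng.exponential(2.0, 80), 2) + 0.01
    status = rng.integers(0, 2, 80)
    status[0] = 1
    entry = np.full(80, time.min() - 1.0)
    s = lk.validate_sample(entry, time, status, "A")
    f = lk.fit_ltrc_cdf(s, hole_correction=False)
    km = lifelines.KaplanMeierFitter().fit(time, status)
    ours = 1.0 - f.cdf(f.atoms)
    theirs = km.survival_function_at_times(f.atoms).to_numpy()
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


def _lynden_bell_brute_force(entry, time, t):
    """Direct product over definitionally computed risk sets (no censoring)."""
    val = 1.0
    for x in np.unique(time):
        if x <= t:
            d = np.sum(time == x)
            r = np.sum((entry <= x) & (x <= time))
            val *= 1.0 - d / r
    return 1.0 - val


def test_matches_lynden_bell_brute_force_without_censoring():
    rng = np.random.default_rng(11)
    entry = rng.uniform(0, 2, 60)
    time = entry + rng.exponential(1.0, 60)
    s = lk.validate_sample(entry, time, np.ones(60), "A")
    f = lk.fit_ltrc_cdf(s, hole_correction=False)
    for t in np.quantile(time, [0.1, 0.35, 0.6, 0.9]):
        assert f.cdf(t) == pytest.approx(
            _lynden_bell_brute_force(entry, time, t), abs=1e-12
        )


@settings(derandomize=True, max_examples=25)
@given(st.randoms(use_true_random=False))
def test_corrected_estimate_dominated_by_uncorrected(r):
    rng = np.random.default_rng(r.randrange(2**32))
    n = rng.integers(2, 40)
    entry = rng.uniform(0, 2, n)
    time = entry + rng.exponential(1.0, n)
    status = rng.integers(0, 2, n)
    status[rng.integers(0, n)] = 1
    s = lk.validate_sample(entry, time, status, "A")
    grid = np.concatenate(([time.min() - 1], np.sort(time), [time.max() + 1]))
    plain = lk.fit_ltrc_cdf(s, hole_correction=False)
    corr = lk.fit_ltrc_cdf(s, hole_correction=True)
    assert np.all(corr.cdf(grid) <= plain.cdf(grid) + CDF_TOL)
    for f in (plain, corr):
        vals = f.cdf(grid)
        assert np.all(np.diff(vals) >= -CDF_TOL)
        assert f.total_mass <= 1 + CDF_TOL


# ---------------------------------------------------------------------------
# truncation CDF and nontruncation probability
# ---------------------------------------------------------------------------


def test_truncation_cdf_equal_weights():
    s = lk.validate_sample([0, 0.5], [1, 2], [1, 1], "A")
    g = lk.fit_truncation_cdf(s, lk.fit_ltrc_cdf(s, hole_correction=False))
    np.testing.assert_allclose(g.cdf([0, 0.5]), [0.5, 1.0], atol=1e-15)
    assert g.total_mass == pytest.approx(1.0)


def test_truncation_cdf_inverse_survival_weights():
    # hole-corrected survival halves at the first event, doubling the second
    # entry's weight: G(0) = 1/3
    s = lk.validate_sample([0, 1.5], [1, 2], [1, 1], "A")
    g = lk.fit_truncation_cdf(s)
    np.testing.assert_allclose(g.cdf([0, 1.5]), [1 / 3, 1.0], atol=1e-15)
    assert lk.estimate_nontruncation(s) == pytest.approx(2 / 3)


def test_truncation_cdf_raises_on_hole():
    # uncorrected fit has a hole at t=1, so S(1.5) = 0
    s = lk.validate_sample([0, 1.5], [1, 2], [1, 1], "A")
    with pytest.raises(lk.SurvivalHoleError):
        lk.fit_truncation_cdf(s, lk.fit_ltrc_cdf(s, hole_correction=False))


def test_truncation_cdf_is_entry_ecdf_when_entries_precede_events():
    s = lk.validate_sample([0, 0.1, 0.2], [1, 2, 3], [1, 1, 1], "A")
    g = lk.fit_truncation_cdf(s, lk.fit_ltrc_cdf(s, hole_correction=False))
    np.testing.assert_allclose(g.mass, [1 / 3] * 3, atol=1e-15)
    assert lk.estimate_nontruncation(
        s, lk.fit_ltrc_cdf(s, hole_correction=False)
    ) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# residual censoring
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "records,atoms,mass",
    [
        ([(0, 2, 0), (0, 5, 0)], [2, 5], [0.5, 0.5]),
        ([(0, 2, 1), (0, 5, 0)], [5], [1.0]),
        ([(0, 3, 1)], [3], [1.0]),
    ],
)
def test_residual_censoring_km(records, atoms, mass):
    # built directly: an all-censored group is fine for estimating Q even
    # though it carries no information about the event-time distribution
    e, t, d = zip(*records)
    sample = lk.LTRCSample(
        np.asarray(e, float), np.asarray(t, float), np.asarray(d, np.int8), "A"
    )
    q = lk.fit_residual_censoring_cdf(sample)
    np.testing.assert_allclose(q.atoms, atoms)
    np.testing.assert_allclose(q.mass, mass, atol=1e-15)
    assert q.is_proper


def test_residual_censoring_ties_events_first():
    # one D-event and one D-censoring at the same residual time: the event
    # uses the full risk set, the censored record only removes itself after
    s = lk.validate_sample([0, 1, 0], [2, 3, 4], [0, 1, 1], "A")
    q = lk.fit_residual_censoring_cdf(s)
    # residuals: 2 (D-event), 2 (D-censored), 4 (D-censored)
    assert q.cdf(2) == pytest.approx(1 / 3)
    assert q.is_proper


# ---------------------------------------------------------------------------
# StepCDF mechanics
# ---------------------------------------------------------------------------


def test_stepcdf_right_continuity_and_bounds():
    f = lk.StepCDF([1.0, 2.0], [0.25, 0.25])
    assert f.cdf(0.999) == 0.0
    assert f.cdf(1.0) == 0.25
    assert f.total_mass == pytest.approx(0.5)
    proper = f.as_proper()
    assert proper.total_mass == pytest.approx(1.0)
    np.testing.assert_allclose(proper.mass, [0.25, 0.75])


def test_stepcdf_sampling_inverse_transform():
    f = lk.StepCDF([1.0, 2.0, 5.0], [0.2, 0.3, 0.5])
    draws = f.sample(np.random.default_rng(0), 20000)
    freqs = [np.mean(draws == a) for a in f.atoms]
    np.testing.assert_allclose(freqs, f.mass, atol=0.02)


def test_stepcdf_rejects_invalid_shapes():
    with pytest.raises(lk.LTRCError):
        lk.StepCDF([2.0, 1.0], [0.5, 0.5])
    with pytest.raises(lk.LTRCError):
        lk.StepCDF([1.0, 2.0], [0.8, 0.8])
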