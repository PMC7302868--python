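"""Relative-risk core: linear expectation, corrections, pooling, variance."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import clockshift as cs
from clockshift.rr import _ratio
from conftest import make_flat_config

SPRING = dt.date(2010, 3, 14)  # US spring shift, a Sunday


def series_from_counts(counts, denominators, start=dt.date(2010, 2, 14),
                       stratum=None):
    counts = np.asarray(counts, float)
    if np.isscalar(denominators):
        denominators = np.full(len(counts), denominators, float)
    return cs.DailySeries("c", stratum or cs.Stratum("F", "21-40"),
                          pd.date_range(start, periods=len(counts)),
                          counts, denominators)


def flat_series(value, denom=1000.0, days=60, start=dt.date(2010, 2, 14)):
    return series_from_counts([value] * days, denom, start)


@pytest.fixture
def cal():
    return cs.ShiftCalendar(rule="us", holidays=frozenset())


class TestLinearExpectation:
    def test_mean_of_comparator_rates(self, cal):
        s = flat_series(0, days=60)
        s.counts[s._pos(dt.date(2010, 3, 3))] = 4    # -14 from Mar 17
        s.counts[s._pos(dt.date(2010, 3, 31))] = 6   # +14
        exp, counts, denoms = cs.linear_expectation(s, dt.date(2010, 3, 17), cal)
        assert exp == pytest.approx((0.004 + 0.006) / 2)
        assert counts == [4, 6] and denoms == [1000, 1000]

    def test_hand_computed_counts(self, cal):
        s = flat_series(0, days=60)
        s.counts[s._pos(dt.date(2010, 3, 3))] = 10
        s.counts[s._pos(dt.date(2010, 3, 31))] = 14
        exp, _, _ = cs.linear_expectation(s, dt.date(2010, 3, 17), cal)
        assert exp == pytest.approx(0.012)

    def test_holiday_comparator_replaced_by_minus_21(self):
        holiday = dt.date(2010, 3, 3)
        cal = cs.ShiftCalendar(rule="us", holidays=frozenset([holiday]))
        s = flat_series(5.0, days=60)
        s.counts[s._pos(holiday)] = 500              # would distort the mean
        s.counts[s._pos(dt.date(2010, 2, 24))] = 7   # -21, used instead
        exp, counts, _ = cs.linear_expectation(s, dt.date(2010, 3, 17), cal)
        assert counts == [7, 5]
        assert exp == pytest.approx((0.007 + 0.005) / 2)

    def test_comparator_outside_series_raises_window_error(self, cal):
        s = flat_series(5.0, days=20)
        with pytest.raises(cs.WindowError):
            cs.linear_expectation(s, dt.date(2010, 2, 16), cal)

    def test_holiday_substitution_leaves_flat_series_unchanged(self):
        cal_h = cs.ShiftCalendar(rule="us", holidays=frozenset([dt.date(2010, 3, 3)]))
        cal_0 = cs.ShiftCalendar(rule="us", holidays=frozenset())
        s = flat_series(5.0, days=60)
        e1, _, _ = cs.linear_expectation(s, dt.date(2010, 3, 17), cal_h)
        e0, _, _ = cs.linear_expectation(s, dt.date(2010, 3, 17), cal_0)
        assert e1 == e0


class TestDayRR:
    def test_null_case_rr_one(self, cal):
        est = cs.day_rr(flat_series(5.0), SPRING, 3, cal, "spring")
        assert est.rr == pytest.approx(1.0)
        assert est.level == "day3"

    def test_hand_computed_ratio(self, cal):
        s = flat_series(0.0)
        target = SPRING + dt.timedelta(days=3)
        s.counts[s._pos(target)] = 15
        s.counts[s._pos(target - dt.timedelta(days=14))] = 10
        s.counts[s._pos(target + dt.timedelta(days=14))] = 10
        est = cs.day_rr(s, SPRING, 3, cal, "spring")
        assert est.rr == pytest.approx(1.5)
        assert est.se_log == pytest.approx(np.sqrt(1 / 15 + 1 / 20))

    def test_day_length_correction_cancels_on_shift_day(self, cal):
        s = flat_series(24.0)
        s.counts[s._pos(SPRING)] = 23.0  # constant hourly rate on a 23-h day
        est = cs.day_rr(s, SPRING, 0, cal, "spring")
        assert est.rr == pytest.approx(1.0, rel=1e-12)

    def test_autumn_shift_day_corrected_by_24_25(self, cal):
        s = flat_series(24.0)
        autumn = dt.date(2010, 11, 7)
        s2 = series_from_counts([24.0] * 60, 1000.0, start=dt.date(2010, 10, 10))
        s2.counts[s2._pos(autumn)] = 25.0
        est = cs.day_rr(s2, autumn, 0, cal, "autumn")
        assert est.rr == pytest.approx(1.0, rel=1e-12)

    def test_bad_offset_rejected(self, cal):
        with pytest.raises(ValueError):
            cs.day_rr(flat_series(5.0), SPRING, 7, cal, "spring")

    def test_zero_expected_with_positive_observed_raises(self, cal):
        s = flat_series(0.0)
        s.counts[s._pos(SPRING + dt.timedelta(days=2))] = 3
        with pytest.raises(cs.UndefinedRRError):
            cs.day_rr(s, SPRING, 2, cal, "spring")

    def test_both_zero_flagged_uninformative(self, cal):
        est = cs.day_rr(flat_series(0.0), SPRING, 2, cal, "spring")
        assert est.uninformative


class TestWeekRR:
    def test_flat_series_gives_one(self, cal):
        est = cs.week_rr(flat_series(7.0), SPRING, cal, "spring")
        # the spring shift-day count is scaled by 24/23, so rr sits just above 1
        assert est.rr == pytest.approx((6 + 24 / 23) / 7)

    def test_hand_computed_week_ratio(self, cal):
        s = flat_series(0.0, denom=1000.0)
        for k in range(7):
            s.counts[s._pos(SPRING + dt.timedelta(days=k))] = 10
            s.counts[s._pos(SPRING + dt.timedelta(days=k - 14))] = 50 / 7
            s.counts[s._pos(SPRING + dt.timedelta(days=k + 14))] = 50 / 7
        s.counts[s._pos(SPRING)] = 10 * 23 / 24  # cancel the day-length factor
        est = cs.week_rr(s, SPRING, cal, "spring")
        assert est.rr == pytest.approx(70 / 50, rel=1e-12)

    def test_monday_start_week_skips_shift_day_correction(self, cal):
        s = flat_series(24.0)
        s.counts[s._pos(SPRING)] = 23.0  # short day; outside a Monday-start week
        est = cs.week_rr(s, SPRING, cal, "spring", week_start_offset=1)
        assert est.rr == pytest.approx(1.0, rel=1e-12)

    def test_recovers_injected_week_effect(self, cal):
        eff = cs.InjectedEffect("c1", "spring", rr=1.1, duration_days=7)
        cfg = make_flat_config(n_patients=60000, hazard=0.02, dst_effects=[eff], seed=21)
        spans, events = cs.simulate_cohort(cfg)
        series, _ = cs.build_series(events, spans, None, cfg.study_window)
        ests = [cs.week_rr(s, SPRING, cal, "spring") for s in series.values()]
        pooled = np.average([e.log_rr for e in ests],
                            weights=[1 / e.se_log**2 for e in ests])
        se = 1 / np.sqrt(sum(1 / e.se_log**2 for e in ests))
        assert abs(pooled - np.log(1.1)) < 4 * se


class TestPoolingAndVariance:
    def test_single_year_identity(self, cal):
        est = cs.day_rr(flat_series(5.0), SPRING, 3, cal, "spring")
        assert cs.pool_years([est]).rr == est.rr

    def test_equal_counts_pool_to_one(self, cal):
        e1 = cs.day_rr(flat_series(5.0), SPRING, 3, cal, "spring")
        assert cs.pool_years([e1, e1]).rr == pytest.approx(1.0)

    def test_opposite_years_cancel(self):
        st_ = cs.Stratum("F", "21-40")
        mk = lambda O, E: cs.RrEstimate("c", st_, "spring", "week", O / E,
                                        np.log(O / E), 0.1, O, E, 2 * E)
        pooled = cs.pool_years([mk(20, 10), mk(10, 20)])
        assert pooled.rr == pytest.approx(1.0)
        assert pooled.n_years == 2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            cs.pool_years([])

    def test_log_variance_delta_method(self):
        assert cs.log_variance(100, [100, 100]) == pytest.approx(0.015)

    def test_log_variance_vanishes_for_large_counts(self):
        assert cs.log_variance(1e8, [1e8, 1e8]) < 1e-7

    def test_zero_count_continuity_correction(self):
        assert cs.log_variance(0, [10, 10]) == pytest.approx(1 / 0.5 + 1 / 21.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(o=st.integers(1, 500), c1=st.integers(1, 500), c2=st.integers(1, 500),
           scale=st.integers(2, 50))
    def test_scale_invariance_of_rr(self, o, c1, c2, scale):
        """Multiplying all counts and denominators by a constant leaves the
        point estimate unchanged."""
        rr1, *_ = _ratio(o, 1000.0, (c1 + c2) / 2 / 1000.0, [c1, c2])
        rr2, *_ = _ratio(o * scale, 1000.0 * scale,
                         (c1 + c2) / 2 / 1000.0, [c1 * scale, c2 * scale])
        assert rr1 == pytest.approx(rr2)


class TestEstimateRr:
    def test_pooled_over_two_years(self, cal):
        # birth years chosen so nobody crosses an age-group boundary mid-study
        cfg = make_flat_config(n_patients=4000, hazard=0.01, seed=13,
                               birth_year_range=(1951, 1985),
                               window=(dt.date(2009, 2, 1), dt.date(2010, 4, 30)))
        spans, events = cs.simulate_cohort(cfg)
        series, _ = cs.build_series(events, spans, None, cfg.study_window)
        ests = cs.estimate_rr(series, cal, [2009, 2010], seasons=("spring",))
        assert all(e.n_years == 2 for e in ests if not e.uninformative)
        assert all(e.season == "spring" and e.level == "week" for e in ests)

    def test_null_calibration_mean_and_variance(self):
        """No structure, no effects: week-level log RRs center at 0 and their
        spread matches the delta-method variance."""
        cal0 = cs.ShiftCalendar(rule="us", holidays=frozenset())
        # ages 21-60 only -> 4 populated strata x 125 classes = 500 units
        cfg = make_flat_config(
            n_patients=30000, classes=[f"c{i:03d}" for i in range(125)], hazard=0.004,
            window=(dt.date(2010, 2, 22), dt.date(2010, 4, 10)), seed=33)
        spans, events = cs.simulate_cohort(cfg)
        series, _ = cs.build_series(events, spans, None, cfg.study_window)
        ests = [e for e in cs.estimate_rr(series, cal0, [2010], seasons=("spring",))
                if not e.uninformative]
        logs = np.array([e.log_rr for e in ests])
        assert len(logs) == 500
        assert abs(logs.mean()) < 0.01
        model_var = np.mean([e.se_log**2 for e in ests])
        assert abs(logs.var() / model_var - 1) < 0.2
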