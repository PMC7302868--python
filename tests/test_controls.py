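"""Negative controls, signal selection rule, excess burden."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

import clockshift as cs
from conftest import make_flat_config


def summary_from_intervals(rows, level=0.99):
    """Construct a frequentist summary with prescribed intervals.

    rows: (class_id, lower, upper); the point estimate is the geometric
    interval midpoint.
    """
    recs = []
    for cid, lo, hi in rows:
        point = np.sqrt(lo * hi)
        recs.append({"class_id": cid, "sex": "F", "age_group": "21-40",
                     "setting": "all_patient", "season": "spring", "level": "week",
                     "log_rr": np.log(point), "se_log": 0.05,
                     "point_rr": point, "lower": lo, "upper": hi,
                     "p_value": 0.5, "selected": False, "method": "freq"})
    return cs.FreqSummary(units=pd.DataFrame(recs), nominal_level=level)


class TestControlDates:
    def test_pseudo_dates_28_days_out(self):
        cal = cs.ShiftCalendar(rule="us", holidays=frozenset())
        dates = dict(((y, s), d) for y, s, d in cs.pseudo_shift_dates(cal, [2010]))
        assert dates[(2010, "spring")] == dt.date(2010, 4, 11)   # 03-14 + 28
        assert dates[(2010, "autumn")] == dt.date(2010, 10, 10)  # 11-07 - 28

    def test_pseudo_dates_preserve_weekday(self):
        cal = cs.ShiftCalendar(rule="us")
        real = cal.shift_dates(range(1995, 2015))
        pseudo = cs.pseudo_shift_dates(cal, range(1995, 2015))
        for (_, _, r), (_, _, p) in zip(real, pseudo):
            assert r.weekday() == p.weekday() == 6

    def test_non_observing_calendar_gives_no_pseudo_dates(self):
        cal = cs.ShiftCalendar(rule="us", observes_dst=False)
        assert cs.pseudo_shift_dates(cal, range(2000, 2010)) == []

    def test_pre_adoption_dates_use_rule_before_cutoff(self):
        cal = cs.ShiftCalendar(region="SE", rule="eu", adoption_year=1980)
        dates = cs.pre_adoption_dates(cal, [1975, 1980, 1985])
        assert [(y, s) for y, s, _ in dates] == [(1975, "spring"), (1975, "autumn")]
        assert dates[0][2] == dt.date(1975, 3, 30)  # last Sunday of March

    def test_pre_adoption_empty_range_warns(self):
        cal = cs.ShiftCalendar(rule="eu", adoption_year=1980)
        with pytest.warns(UserWarning, match="pre-adoption"):
            assert cs.pre_adoption_dates(cal, [1990, 1991]) == []


@pytest.fixture(scope="module")
def cohort_series():
    cfg = make_flat_config(n_patients=8000,
                           classes=[f"c{i}" for i in range(5)], hazard=0.01,
                           window=(dt.date(2010, 2, 1), dt.date(2010, 5, 20)),
                           seed=17)
    spans, events = cs.simulate_cohort(cfg)
    series, _ = cs.build_series(events, spans, None, cfg.study_window)
    return cfg, series


class TestRunControl:

    def test_degenerate_offset_zero_equals_real_run(self, cohort_series):
        cfg, series = cohort_series
        spec = cs.ControlSpec(kind="pseudo_date", offset_days=0)
        ctl_est, _ = cs.run_control(series, spec, cfg.calendar, [2010], ("spring",))
        real_est = cs.estimate_rr(series, cfg.calendar, [2010], ("spring",))
        for c, r in zip(ctl_est, real_est):
            assert c.is_control and not r.is_control
            assert c.rr == pytest.approx(r.rr)
            assert c.se_log == pytest.approx(r.se_log)

    def test_control_estimates_flagged(self, cohort_series):
        cfg, series = cohort_series
        spec = cs.ControlSpec(kind="pseudo_date")
        ests, summary = cs.run_control(series, spec, cfg.calendar, [2010], ("spring",))
        assert all(e.is_control for e in ests)
        assert len(summary.units) == len([e for e in ests if not e.uninformative])

    def test_unknown_control_kind_rejected(self):
        with pytest.raises(ValueError):
            cs.ControlSpec(kind="placebo")


class TestSelectSignals:
    def test_rule_examples(self):
        real = summary_from_intervals([("a", 1.05, 1.12), ("b", 1.05, 1.12),
                                       ("c", 0.90, 0.97), ("d", 0.95, 1.04)])
        ctrl = summary_from_intervals([("a", 0.97, 1.03), ("b", 1.02, 1.08),
                                       ("c", 0.96, 1.02), ("d", 0.95, 1.04)])
        table = cs.select_signals(real, ctrl, level=0.99, exclude_ambiguous=False)
        got = dict(zip(table.rows["class_id"], table.rows["direction"]))
        assert got == {"a": "up", "c": "down"}  # b: control also up; d: not flagged

    def test_top_n_caps_by_effect_size(self):
        rrs = np.linspace(1.02, 1.40, 40)
        real = summary_from_intervals([(f"c{i:02d}", r * 0.99, r * 1.01)
                                       for i, r in enumerate(rrs)])
        ctrl = summary_from_intervals([(f"c{i:02d}", 0.99, 1.01) for i in range(40)])
        table = cs.select_signals(real, ctrl, level=0.99, top_n=30,
                                  exclude_ambiguous=False)
        assert len(table) == 30
        kept = set(table.rows["class_id"])
        assert kept == {f"c{i:02d}" for i in range(10, 40)}  # 30 largest RRs

    def test_swap_real_control_selects_complement(self):
        real = summary_from_intervals([("a", 1.05, 1.12), ("b", 0.98, 1.02)])
        ctrl = summary_from_intervals([("a", 0.98, 1.02), ("b", 1.05, 1.12)])
        t1 = cs.select_signals(real, ctrl, 0.99, exclude_ambiguous=False)
        t2 = cs.select_signals(ctrl, real, 0.99, exclude_ambiguous=False)
        assert set(t1.rows["class_id"]) == {"a"}
        assert set(t2.rows["class_id"]) == {"b"}

    def test_ambiguous_classes_excluded(self):
        real = summary_from_intervals([("amb", 1.05, 1.12), ("ok", 1.05, 1.12)])
        ctrl = summary_from_intervals([("amb", 0.98, 1.02), ("ok", 0.98, 1.02)])
        table = cs.select_signals(real, ctrl, 0.99, exclude_ambiguous=True,
                                  ambiguous={"amb"})
        assert set(table.rows["class_id"]) == {"ok"}

    def test_unit_missing_from_control_excluded_with_warning(self):
        real = summary_from_intervals([("a", 1.05, 1.12), ("b", 1.05, 1.12)])
        ctrl = summary_from_intervals([("a", 0.98, 1.02)])
        with pytest.warns(UserWarning, match="missing"):
            table = cs.select_signals(real, ctrl, 0.99, exclude_ambiguous=False)
        assert set(table.rows["class_id"]) == {"a"}


class TestExcessBurden:
    def _signals_and_estimates(self, rr, weekly_expected=100.0, n_years=1):
        real = summary_from_intervals([("a", rr * 0.99, rr * 1.01)])
        ctrl = summary_from_intervals([("a", 0.99, 1.01)])
        table = cs.select_signals(real, ctrl, 0.99, exclude_ambiguous=False)
        est = pd.DataFrame([{
            "class_id": "a", "sex": "F", "age_group": "21-40",
            "setting": "all_patient", "season": "spring", "level": "week",
            "rr": rr, "expected": weekly_expected * n_years, "n_years": n_years,
            "is_control": False}])
        return table, est

    def test_formula(self):
        table, est = self._signals_and_estimates(1.1)
        out = cs.excess_burden(table, est, population_scale=1.0)
        point = float(table.rows["point_rr_real"].iloc[0])
        assert out["excess_per_shift"].iloc[0] == pytest.approx((point - 1) * 100)

    def test_null_rr_gives_zero(self):
        rows = pd.DataFrame([{
            "class_id": "a", "sex": "F", "age_group": "21-40",
            "setting": "all_patient", "season": "spring", "level": "week",
            "direction": "up", "point_rr_real": 1.0}])
        table = cs.SignalTable(rows=rows, level=0.99, top_n=None,
                               exclude_ambiguous=False)
        _, est = self._signals_and_estimates(1.0)
        out = cs.excess_burden(table, est)
        assert out["excess_per_shift"].iloc[0] == pytest.approx(0.0)

    def test_population_scale_linearity(self):
        table, est = self._signals_and_estimates(1.2)
        a = cs.excess_burden(table, est, population_scale=1.0)
        b = cs.excess_burden(table, est, population_scale=2.0)
        assert b["excess_per_shift"].iloc[0] == pytest.approx(
            2 * a["excess_per_shift"].iloc[0])
        assert b.attrs["total_up"] == pytest.approx(2 * a.attrs["total_up"])

    def test_pooled_years_divided_out(self):
        table, est = self._signals_and_estimates(1.1, weekly_expected=100, n_years=4)
        out = cs.excess_burden(table, est)
        assert out["expected_weekly_per_shift"].iloc[0] == pytest.approx(100.0)

    def test_missing_baseline_skipped_with_warning(self):
        table, est = self._signals_and_estimates(1.1)
        est = est[est["class_id"] != "a"]
        with pytest.warns(UserWarning, match="baseline"):
            out = cs.excess_burden(table, est)
        assert len(out) == 0
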