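"""Relative risk against the same-weekday linear expectation.

The counterfactual for a day of interest is the *linear expectation*: the
mean diagnosis rate on the same weekday two weeks before and two weeks
after.  Day-level RRs cover each of the seven days starting at a DST shift;
the week-level RR collapses the whole post-shift week and compares it with
the two comparator weeks.

Two corrections are applied:

* **day length** — the spring shift day has 23 hours and the autumn shift day
  25; observed counts on a shift day are rescaled by ``24 / day_length`` so a
  constant hourly process yields RR 1;
* **holidays** — a comparator that falls on a listed holiday is replaced by
  the same weekday one week further out (±21 days), preserving the weekday
  structure of the design.

Uncertainty is delta-method Poisson variance on the log scale,
``1/O + 1/(C1 + C2)``, with a 0.5 continuity correction added to every count
when any count is zero.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .calendars import Season, ShiftCalendar
from .incidence import DailySeries, Stratum

__all__ = [
    "RrEstimate", "WindowError", "UndefinedRRError", "InsufficientComparatorError",
    "linear_expectation", "day_rr", "week_rr", "pool_years", "log_variance",
    "estimate_rr", "estimates_to_frame",
]


class WindowError(KeyError):
    """A comparator or target date falls outside the series index."""


class UndefinedRRError(ValueError):
    """Expected rate is zero while the observed count is positive."""


class InsufficientComparatorError(ValueError):
    """All comparators excluded (holiday rule) for a target."""


@dataclass(frozen=True)
class RrEstimate:
    class_id: str
    stratum: Stratum
    season: Season
    level: str                      # "day0".."day6" or "week"
    rr: float
    log_rr: float
    se_log: float
    observed_count: float           # day-length corrected
    expected_count: float
    comparator_count: float         # raw sum over comparators
    n_years: int = 1
    method: str = "raw"
    is_control: bool = False
    uninformative: bool = False


def log_variance(observed: float, comparator_counts: Sequence[float]) -> float:
    """Delta-method variance of log RR for the two-comparator design."""
    counts = [float(observed), *map(float, comparator_counts)]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if any(c == 0 for c in counts):
        counts = [c + 0.5 for c in counts]
    o, comps = counts[0], counts[1:]
    return 1.0 / o + 1.0 / sum(comps)


def _comparator_date(series: DailySeries, target: dt.date, offset: int,
                     calendar: ShiftCalendar, policy: str) -> dt.date | None:
    """Resolve one comparator, applying the holiday substitution rule."""
    step = 7 if offset > 0 else -7
    date = target + dt.timedelta(days=offset)
    for _ in range(3):  # at most two extra weeks out
        if not calendar.is_holiday(date):
            return date
        if policy == "drop":
            return None
        date = date + dt.timedelta(days=step)
    raise InsufficientComparatorError(
        f"no non-holiday comparator near {target} (offset {offset})")


def linear_expectation(series: DailySeries, target: dt.date,
                       calendar: ShiftCalendar | None = None,
                       offsets: Sequence[int] = (-14, 14),
                       holiday_policy: str = "substitute",
                       ) -> tuple[float, list[float], list[float]]:
    """Expected diagnosis rate at ``target``: mean of the same-weekday
    comparator rates.  Returns (expected rate, comparator counts,
    comparator denominators)."""
    calendar = calendar or ShiftCalendar(holidays=frozenset())
    counts, denoms = [], []
    for off in offsets:
        date = _comparator_date(series, target, off, calendar, holiday_policy)
        if date is None:
            continue
        assert date.weekday() == target.weekday(), "comparator must share the target weekday"
        try:
            counts.append(series.count_on(date))
            denoms.append(series.denominator_on(date))
        except KeyError as exc:
            raise WindowError(str(exc)) from None
    if not counts:
        raise InsufficientComparatorError(f"no usable comparator for {target}")
    if any(d == 0 for d in denoms):
        raise UndefinedRRError(f"zero enrollees in a comparator for {target}")
    rates = [c / d for c, d in zip(counts, denoms)]
    return float(np.mean(rates)), counts, denoms


def _ratio(obs_corr: float, obs_denom: float, exp_rate: float,
           comp_counts: Sequence[float]) -> tuple[float, float, float, bool]:
    """(rr, log_rr, se_log, uninformative) with zero-count handling."""
    comp_total = float(sum(comp_counts))
    exp_count = exp_rate * obs_denom
    if exp_rate == 0 and obs_corr == 0:
        return np.nan, np.nan, np.nan, True
    if exp_rate == 0:
        raise UndefinedRRError("expected rate is zero with positive observed count")
    if obs_corr == 0 or comp_total == 0:
        # continuity correction on the point estimate mirrors the variance rule
        rr = (obs_corr + 0.5) / (exp_count + 0.5)
    else:
        rr = obs_corr / exp_count
    se = float(np.sqrt(log_variance(obs_corr, comp_counts)))
    return float(rr), float(np.log(rr)), se, False


def day_rr(series: DailySeries, shift_date: dt.date, k: int,
           calendar: ShiftCalendar, season: Season,
           holiday_policy: str = "substitute", is_control: bool = False) -> RrEstimate:
    """Day-level RR for the k-th day (0..6) after a shift date.

    On the shift day itself the observed count is rescaled by
    ``24/23`` (spring) or ``24/25`` (autumn); at pseudo or pre-adoption dates
    the calendar reports 24-hour days and no correction occurs.
    """
    if not 0 <= k <= 6:
        raise ValueError("day offset k must lie in 0..6")
    target = shift_date + dt.timedelta(days=k)
    try:
        obs = series.count_on(target)
        denom = series.denominator_on(target)
    except KeyError as exc:
        raise WindowError(str(exc)) from None
    if denom == 0:
        raise UndefinedRRError(f"zero enrollees on {target}")
    obs_corr = obs * 24.0 / calendar.day_length_hours(target)
    exp_rate, comp_counts, _ = linear_expectation(
        series, target, calendar, holiday_policy=holiday_policy)
    rr, log_rr, se, uninf = _ratio(obs_corr, denom, exp_rate, comp_counts)
    return RrEstimate(series.class_id, series.stratum, season, f"day{k}",
                      rr, log_rr, se, obs_corr, exp_rate * denom,
                      float(sum(comp_counts)), 1, "raw", is_control, uninf)


def _week_totals(series: DailySeries, start: dt.date,
                 calendar: ShiftCalendar) -> tuple[float, float]:
    """Day-length-corrected count and denominator summed over start..start+6."""
    count = 0.0
    denom = 0.0
    for k in range(7):
        d = start + dt.timedelta(days=k)
        try:
            count += series.count_on(d) * 24.0 / calendar.day_length_hours(d)
            denom += series.denominator_on(d)
        except KeyError as exc:
            raise WindowError(str(exc)) from None
    return count, denom


def week_rr(series: DailySeries, shift_date: dt.date, calendar: ShiftCalendar,
            season: Season, holiday_policy: str = "substitute",
            is_control: bool = False, week_start_offset: int = 0) -> RrEstimate:
    """Week-level RR: the post-shift week against the mean of the two
    comparator weeks two weeks before and after.

    The week starts at the shift Sunday by default; ``week_start_offset=1``
    starts it on the Monday after (the shift-day correction then never
    enters the weekly sums).
    """
    start = shift_date + dt.timedelta(days=week_start_offset)
    obs, obs_denom = _week_totals(series, start, calendar)
    if obs_denom == 0:
        raise UndefinedRRError(f"zero enrollees in week of {shift_date}")
    comp_counts, comp_rates = [], []
    for off in (-14, 14):
        comp_start = _comparator_date(series, start, off, calendar,
                                      "substitute" if holiday_policy == "substitute" else "drop")
        if comp_start is None:
            continue
        c, d = _week_totals(series, comp_start, calendar)
        if d == 0:
            raise UndefinedRRError(f"zero enrollees in comparator week of {start}")
        comp_counts.append(c)
        comp_rates.append(c / d)
    if not comp_rates:
        raise InsufficientComparatorError(f"no usable comparator week for {shift_date}")
    exp_rate = float(np.mean(comp_rates))
    rr, log_rr, se, uninf = _ratio(obs, obs_denom, exp_rate, comp_counts)
    return RrEstimate(series.class_id, series.stratum, season, "week",
                      rr, log_rr, se, obs, exp_rate * obs_denom,
                      float(sum(comp_counts)), 1, "raw", is_control, uninf)


def pool_years(estimates: Sequence[RrEstimate]) -> RrEstimate:
    """Pool per-year estimates by summing observed and expected counts."""
    if not estimates:
        raise ValueError("no estimates to pool")
    first = estimates[0]
    for e in estimates[1:]:
        if (e.class_id, e.stratum, e.season, e.level) != (
                first.class_id, first.stratum, first.season, first.level):
            raise ValueError("pool_years requires matching class/stratum/season/level")
    usable = [e for e in estimates if not e.uninformative]
    if not usable:
        return replace(first, n_years=len(estimates))
    O = sum(e.observed_count for e in usable)
    E = sum(e.expected_count for e in usable)
    C = sum(e.comparator_count for e in usable)
    if E == 0 and O == 0:
        return replace(first, rr=np.nan, log_rr=np.nan, se_log=np.nan,
                       observed_count=0.0, expected_count=0.0, comparator_count=C,
                       n_years=len(estimates), uninformative=True)
    rr = (O + 0.5) / (E + 0.5) if (O == 0 or C == 0) else O / E
    se = float(np.sqrt(log_variance(O, [C])))
    return replace(first, rr=float(rr), log_rr=float(np.log(rr)), se_log=se,
                   observed_count=float(O), expected_count=float(E),
                   comparator_count=float(C), n_years=len(usable), uninformative=False)


def estimate_rr(series_map: dict[tuple[str, Stratum], DailySeries],
                calendar: ShiftCalendar,
                years: Iterable[int],
                seasons: Sequence[Season] = ("spring", "autumn"),
                level: Literal["week", "day"] = "week",
                shift_dates: Sequence[tuple[int, Season, dt.date]] | None = None,
                holiday_policy: str = "substitute",
                is_control: bool = False,
                skip_missing: bool = True) -> list[RrEstimate]:
    """Pooled RR estimates for every series, at real or supplied shift dates.

    ``shift_dates`` overrides the calendar's own dates (negative controls);
    years whose analysis window falls outside a series are skipped when
    ``skip_missing``.
    """
    dates = list(shift_dates) if shift_dates is not None else calendar.shift_dates(years)
    out: list[RrEstimate] = []
    levels = ["week"] if level == "week" else [f"day{k}" for k in range(7)]
    for (cid, stratum), series in sorted(series_map.items(),
                                         key=lambda kv: (kv[0][0], kv[0][1].label)):
        for season in seasons:
            season_dates = [d for (_, s, d) in dates if s == season]
            for lv in levels:
                yearly: list[RrEstimate] = []
                for d in season_dates:
                    try:
                        if lv == "week":
                            est = week_rr(series, d, calendar, season,
                                          holiday_policy, is_control)
                        else:
                            est = day_rr(series, d, int(lv[3:]), calendar, season,
                                         holiday_policy, is_control)
                    except (WindowError, UndefinedRRError, InsufficientComparatorError):
                        if skip_missing:
                            continue
                        raise
                    yearly.append(est)
                if yearly:
                    out.append(pool_years(yearly))
    return out


def estimates_to_frame(estimates: Iterable[RrEstimate]) -> pd.DataFrame:
    """Flat table of estimates (one row per class/stratum/season/level)."""
    rows = [{
        "class_id": e.class_id, "sex": e.stratum.sex,
        "age_group": e.stratum.age_group, "setting": e.stratum.setting,
        "season": e.season, "level": e.level, "rr": e.rr, "log_rr": e.log_rr,
        "se_log": e.se_log, "observed": e.observed_count,
        "expected": e.expected_count, "comparators": e.comparator_count,
        "n_years": e.n_years, "method": e.method, "is_control": e.is_control,
        "uninformative": e.uninformative,
    } for e in estimates]
    return pd.DataFrame(rows)
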