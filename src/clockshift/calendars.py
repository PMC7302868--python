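"""DST shift calendars: statutory clock-change dates, adoption years, holidays.

The spring shift produces a 23-hour day and the autumn shift a 25-hour day.
Built-in rules:

``us_post2007``
    Second Sunday of March / first Sunday of November (Energy Policy Act).
``us_pre2007``
    First Sunday of April / last Sunday of October.
``us``
    Selects the pre- or post-2007 rule by year.
``eu``
    Last Sunday of March / last Sunday of October.

A calendar with ``observes_dst=False`` yields no shift dates at all, which is
how the non-observing-region negative control is expressed.  ``adoption_year``
truncates the rule output (e.g. Sweden adopted DST in 1980); the would-have-been
dates before adoption are still available for the pre-adoption control.
"""
from __future__ import annotations

import calendar as _cal
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Literal

from dateutil.easter import easter

Season = Literal["spring", "autumn"]
SPRING_HOURS = 23.0
AUTUMN_HOURS = 25.0


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    """n-th (1-based) given weekday of a month; n=-1 means last."""
    days = [d for d in range(1, _cal.monthrange(year, month)[1] + 1)
            if dt.date(year, month, d).weekday() == weekday]
    return dt.date(year, month, days[n if n < 0 else n - 1])


_SUN = 6


def _rule_dates(rule: str, year: int) -> tuple[dt.date, dt.date]:
    if rule == "us":
        rule = "us_post2007" if year >= 2007 else "us_pre2007"
    if rule == "us_post2007":
        return _nth_weekday(year, 3, _SUN, 2), _nth_weekday(year, 11, _SUN, 1)
    if rule == "us_pre2007":
        return _nth_weekday(year, 4, _SUN, 1), _nth_weekday(year, 10, _SUN, -1)
    if rule == "eu":
        return _nth_weekday(year, 3, _SUN, -1), _nth_weekday(year, 10, _SUN, -1)
    raise ValueError(f"unknown DST rule {rule!r}")


@dataclass
class ShiftCalendar:
    """Region-specific DST configuration.

    ``explicit_dates`` overrides the rule for listed years; otherwise dates
    come from ``rule``.  ``holidays`` participate in the comparator
    substitution of the RR estimator.
    """

    region: str = "US"
    rule: str = "us"
    adoption_year: int = 1918
    observes_dst: bool = True
    holidays: frozenset[dt.date] = frozenset()
    explicit_dates: dict[int, tuple[dt.date, dt.date]] = field(default_factory=dict)

    def year_dates(self, year: int, *, ignore_adoption: bool = False) -> tuple[dt.date, dt.date]:
        """(spring, autumn) shift dates the rule prescribes for ``year``,
        regardless of observance (used by the pre-adoption control when
        ``ignore_adoption``)."""
        if year in self.explicit_dates:
            spring, autumn = self.explicit_dates[year]
        else:
            spring, autumn = _rule_dates(self.rule, year)
        return spring, autumn

    def shift_dates(self, years: Iterable[int]) -> list[tuple[int, Season, dt.date]]:
        """Observed (year, season, date) triples; empty when the region does
        not observe DST or before the adoption year."""
        out: list[tuple[int, Season, dt.date]] = []
        if not self.observes_dst:
            return out
        for year in years:
            if year < self.adoption_year:
                continue
            spring, autumn = self.year_dates(year)
            out.append((year, "spring", spring))
            out.append((year, "autumn", autumn))
        return out

    def day_length_hours(self, date: dt.date) -> float:
        """24, except 23 on an observed spring shift day and 25 on autumn."""
        if not self.observes_dst or date.year < self.adoption_year:
            return 24.0
        spring, autumn = self.year_dates(date.year)
        if date == spring:
            return SPRING_HOURS
        if date == autumn:
            return AUTUMN_HOURS
        return 24.0

    def is_holiday(self, date: dt.date) -> bool:
        return date in self.holidays


def us_holidays(years: Iterable[int]) -> frozenset[dt.date]:
    """A plain US holiday list: fixed-date federal holidays plus Easter and
    the floating Memorial Day / Labor Day / Thanksgiving."""
    out: set[dt.date] = set()
    for y in years:
        out |= {
            dt.date(y, 1, 1), dt.date(y, 7, 4), dt.date(y, 12, 24),
            dt.date(y, 12, 25), dt.date(y, 12, 31),
            easter(y),
            _nth_weekday(y, 5, 0, -1),   # Memorial Day
            _nth_weekday(y, 9, 0, 1),    # Labor Day
            _nth_weekday(y, 11, 3, 4),   # Thanksgiving
        }
    return frozenset(out)
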