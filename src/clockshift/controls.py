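"""Negative controls, automatic signal selection, excess burden.

Three negative controls re-run the identical estimation pipeline where no
DST effect can exist:

* ``pseudo_date`` — shift dates moved 28 days *after* the real spring shift
  and 28 days *before* the real autumn shift (weekday preserved);
* ``pre_adoption`` — would-have-been shift dates in years before the region
  adopted DST (Sweden: 1980);
* ``non_observing_region`` — the same dates, applied to a cohort from a
  region that does not change its clocks.

A condition x stratum is *selected* as an up-signal when its real interval
lies entirely above 1 at the chosen credible level while the paired control
interval does not, and symmetrically for down-signals.  Selected signals are
ranked by effect size (|log point estimate|) and capped per direction.
"""
from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .calendars import Season, ShiftCalendar
from .incidence import DailySeries, Stratum
from .rr import RrEstimate, estimate_rr, estimates_to_frame
from .shrinkage import (FreqSummary, PosteriorSummary, ShrinkageConfig,
                        credible_flags, fcr_adjust, fit_hierarchical,
                        freq_estimate, freq_flags)
from .taxonomy import TaxonomyMap

ControlKind = Literal["pseudo_date", "pre_adoption", "non_observing_region"]
_UNIT_COLS = ["class_id", "sex", "age_group", "setting", "season", "level"]


@dataclass(frozen=True)
class ControlSpec:
    kind: ControlKind
    offset_days: int = 28        #: pseudo_date: +offset in spring, -offset in autumn
    cutoff_year: int | None = None  #: pre_adoption: defaults to the calendar's adoption year

    def __post_init__(self) -> None:
        if self.kind not in ("pseudo_date", "pre_adoption", "non_observing_region"):
            raise ValueError(f"unknown control kind {self.kind!r}")


def pseudo_shift_dates(calendar: ShiftCalendar, years: Iterable[int],
                       offset_days: int = 28) -> list[tuple[int, Season, dt.date]]:
    """Pseudo dates 28 days after spring / before autumn real shifts; a
    multiple of 7 preserves the shift weekday."""
    out = []
    for year, season, date in calendar.shift_dates(years):
        delta = offset_days if season == "spring" else -offset_days
        out.append((year, season, date + dt.timedelta(days=delta)))
    return out


def pre_adoption_dates(calendar: ShiftCalendar, years: Iterable[int],
                       cutoff_year: int | None = None) -> list[tuple[int, Season, dt.date]]:
    """Would-have-been shift dates strictly before the adoption year."""
    cutoff = calendar.adoption_year if cutoff_year is None else cutoff_year
    out: list[tuple[int, Season, dt.date]] = []
    for year in years:
        if year >= cutoff:
            continue
        spring, autumn = calendar.year_dates(year, ignore_adoption=True)
        out.append((year, "spring", spring))
        out.append((year, "autumn", autumn))
    if not out:
        warnings.warn("no pre-adoption years in the requested range", stacklevel=2)
    return out


def run_control(series_map: dict[tuple[str, Stratum], DailySeries],
                control: ControlSpec, calendar: ShiftCalendar,
                years: Sequence[int], seasons: Sequence[Season] = ("spring", "autumn"),
                level: str = "week",
                shrinkage_config: ShrinkageConfig | None = None,
                holiday_policy: str = "substitute",
                ) -> tuple[list[RrEstimate], PosteriorSummary]:
    """Execute the identical RR + shrinkage pipeline at control dates.

    For ``non_observing_region`` the supplied series must come from the
    non-observing cohort; the real calendar provides the dates while the
    analysis applies no day-length correction (those days are 24 h there).
    """
    analysis_cal = calendar
    if control.kind == "pseudo_date":
        dates = pseudo_shift_dates(calendar, years, control.offset_days)
    elif control.kind == "pre_adoption":
        dates = pre_adoption_dates(calendar, years, control.cutoff_year)
    else:
        dates = calendar.shift_dates(years)
        analysis_cal = _dc_replace(calendar, observes_dst=False)
    estimates = estimate_rr(series_map, analysis_cal, years, seasons,
                            level=level, shift_dates=dates,
                            holiday_policy=holiday_policy, is_control=True)
    usable = [e for e in estimates if not e.uninformative]
    summary = fit_hierarchical(usable, shrinkage_config)
    return estimates, summary


# -- signal selection -----------------------------------------------------

@dataclass
class SignalTable:
    rows: pd.DataFrame
    level: float
    top_n: int | None
    exclude_ambiguous: bool
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)


def _flags_points(summary: PosteriorSummary | FreqSummary, level: float) -> pd.DataFrame:
    if isinstance(summary, PosteriorSummary):
        df = summary.units[_UNIT_COLS].copy()
        df["flag"] = credible_flags(summary, level).to_numpy()
        df["point_rr"] = summary.units["post_mean_rr"].to_numpy()
        df["log_point"] = summary.units["post_mean_log"].to_numpy()
        iv = summary.interval(level)
        df["lower"] = iv.iloc[:, 0].to_numpy()
        df["upper"] = iv.iloc[:, 1].to_numpy()
        return df
    df = summary.units[_UNIT_COLS].copy()
    df["flag"] = freq_flags(summary).to_numpy()
    df["point_rr"] = summary.units["point_rr"].to_numpy()
    df["log_point"] = summary.units["log_rr"].to_numpy()
    lo = "adj_lower" if "adj_lower" in summary.units.columns else "lower"
    hi = "adj_upper" if "adj_upper" in summary.units.columns else "upper"
    df["lower"] = summary.units[lo].to_numpy()
    df["upper"] = summary.units[hi].to_numpy()
    return df


def _ambiguous_lookup(ambiguous) -> set[str]:
    if ambiguous is None:
        return set()
    if isinstance(ambiguous, TaxonomyMap):
        return {cid for cid, cc in ambiguous.classes.items() if cc.ambiguous_flag}
    return set(ambiguous)


def select_signals(real: PosteriorSummary | FreqSummary,
                   control: PosteriorSummary | FreqSummary,
                   level: float = 0.999, top_n: int | None = 30,
                   exclude_ambiguous: bool = True,
                   ambiguous: TaxonomyMap | Iterable[str] | None = None) -> SignalTable:
    """Signals significant in the real analysis and not in its control.

    Up-signals: real lower bound > 1 while the control is not flagged up
    (and vice versa for down-signals).  Both directions are ranked by
    |log point estimate| and capped at ``top_n`` per direction.
    """
    r = _flags_points(real, level)
    c = _flags_points(control, level)
    merged = r.merge(c, on=_UNIT_COLS, how="left", suffixes=("_real", "_control"),
                     indicator=True)
    missing = merged["_merge"] != "both"
    if missing.any():
        warnings.warn(f"{int(missing.sum())} unit(s) missing from the control run "
                      "were excluded from selection", stacklevel=2)
        merged = merged[~missing]
    amb = _ambiguous_lookup(ambiguous)
    if exclude_ambiguous and amb:
        merged = merged[~merged["class_id"].isin(amb)]

    up = merged[(merged["flag_real"] == "up") & (merged["flag_control"] != "up")]
    down = merged[(merged["flag_real"] == "down") & (merged["flag_control"] != "down")]
    parts = []
    for direction, block in (("up", up), ("down", down)):
        block = block.assign(direction=direction,
                             effect_size=block["log_point_real"].abs())
        block = block.sort_values("effect_size", ascending=False, kind="stable")
        if top_n is not None:
            block = block.head(top_n)
        parts.append(block)
    rows = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    rows = rows.drop(columns=["_merge"], errors="ignore")
    rows["rank"] = rows.groupby("direction")["effect_size"].rank(
        ascending=False, method="first").astype(int)
    return SignalTable(rows=rows.reset_index(drop=True), level=level, top_n=top_n,
                       exclude_ambiguous=exclude_ambiguous,
                       metadata={"n_up": int((rows["direction"] == "up").sum()) if len(rows) else 0,
                                 "n_down": int((rows["direction"] == "down").sum()) if len(rows) else 0})


# -- excess burden --------------------------------------------------------

def excess_burden(signals: SignalTable,
                  estimates: Sequence[RrEstimate] | pd.DataFrame,
                  population_scale: float = 1.0) -> pd.DataFrame:
    """Excess incidences per shift attributable to each selected signal.

    per-signal excess = (RR - 1) x expected post-shift-week count per shift
    x ``population_scale`` (a linear factor, e.g. target population divided
    by cohort size).  Totals are reported separately for up- and
    down-signals; a signal without a matching baseline estimate is skipped
    with a warning.
    """
    est = estimates if isinstance(estimates, pd.DataFrame) else estimates_to_frame(estimates)
    est = est[~est["is_control"]]
    key = est.set_index(_UNIT_COLS)
    rows = []
    for _, sig in signals.rows.iterrows():
        k = tuple(sig[c] for c in _UNIT_COLS)
        if k not in key.index:
            warnings.warn(f"signal {k} lacks a baseline estimate; skipped", stacklevel=2)
            continue
        base = key.loc[k]
        weekly = float(base["expected"]) / max(int(base["n_years"]), 1)
        excess = (float(sig["point_rr_real"]) - 1.0) * weekly * population_scale
        rows.append({**{c: sig[c] for c in _UNIT_COLS}, "direction": sig["direction"],
                     "rr": float(sig["point_rr_real"]),
                     "expected_weekly_per_shift": weekly, "excess_per_shift": excess})
    out = pd.DataFrame(rows)
    if len(out):
        totals = out.groupby("direction")["excess_per_shift"].sum()
        out.attrs["total_up"] = float(totals.get("up", 0.0))
        out.attrs["total_down"] = float(totals.get("down", 0.0))
    else:
        out.attrs["total_up"] = out.attrs["total_down"] = 0.0
    return out
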