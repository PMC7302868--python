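"""Aggregation of diagnosis events into per-condition, per-stratum daily series.

The unit of relative-risk estimation is a :class:`DailySeries`: a contiguous
date index with, per day, the number of diagnoses of one condition class in
one sex x age-group stratum and the number of enrollees at risk that day.
Age is evaluated at the event date (calendar-year precision from the birth
year), so a patient crossing an age-group boundary mid-study contributes to
the denominators of both groups, on the appropriate days.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .taxonomy import IcdCode, TaxonomyMap

SEXES = ("F", "M")
#: fine partition used where the data are large enough; "0-20" is the coarse
#: union of the first two, used where the finer split is unavailable
AGE_GROUPS_FINE = ("0-10", "11-20", "21-40", "41-60", "60+")
AGE_GROUPS_COARSE = ("0-20", "21-40", "41-60", "60+")
_BOUNDS = {
    "0-10": (0, 10), "11-20": (11, 20), "0-20": (0, 20),
    "21-40": (21, 40), "41-60": (41, 60), "60+": (61, 200),
}
SETTINGS = ("inpatient", "all_patient")


class UndefinedRateError(ZeroDivisionError):
    """Diagnosis rate requested on a day with zero enrollees."""


def age_group_of(age: int, coarse: bool = False) -> str:
    groups = AGE_GROUPS_COARSE if coarse else AGE_GROUPS_FINE
    for g in groups:
        lo, hi = _BOUNDS[g]
        if lo <= age <= hi:
            return g
    raise ValueError(f"age {age} outside all groups")


@dataclass(frozen=True)
class Stratum:
    sex: str
    age_group: str
    setting: str = "all_patient"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in _BOUNDS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")

    @property
    def label(self) -> str:
        return f"{self.sex}/{self.age_group}/{self.setting}"


def default_strata(coarse: bool = False, setting: str = "all_patient") -> list[Stratum]:
    groups = AGE_GROUPS_COARSE if coarse else AGE_GROUPS_FINE
    return [Stratum(s, g, setting) for s in SEXES for g in groups]


@dataclass
class DailySeries:
    """Date-indexed counts and enrollee denominators for one class x stratum."""

    class_id: str
    stratum: Stratum
    dates: pd.DatetimeIndex
    counts: np.ndarray
    denominators: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.denominators = np.asarray(self.denominators, dtype=float)
        if not (len(self.dates) == len(self.counts) == len(self.denominators)):
            raise ValueError("dates, counts and denominators must align")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("date index must be contiguous daily")
        if (self.counts < 0).any() or (self.denominators < 0).any():
            raise ValueError("counts and denominators must be non-negative")

    def _pos(self, date: dt.date) -> int:
        ts = pd.Timestamp(date)
        if ts < self.dates[0] or ts > self.dates[-1]:
            raise KeyError(f"{date} outside series window "
                           f"[{self.dates[0].date()}, {self.dates[-1].date()}]")
        return int((ts - self.dates[0]).days)

    def count_on(self, date: dt.date) -> float:
        return float(self.counts[self._pos(date)])

    def denominator_on(self, date: dt.date) -> float:
        return float(self.denominators[self._pos(date)])

    def rate_on(self, date: dt.date) -> float:
        """Diagnoses per enrollee on ``date`` (the diagnosis rate)."""
        i = self._pos(date)
        if self.denominators[i] == 0:
            raise UndefinedRateError(f"zero enrollees on {date} for "
                                     f"{self.class_id} {self.stratum.label}")
        return float(self.counts[i] / self.denominators[i])


def diagnosis_rate(series: DailySeries, date: dt.date) -> float:
    return series.rate_on(date)


# -- event classification -------------------------------------------------

def classify_events(events: pd.DataFrame, taxonomy: TaxonomyMap) -> pd.DataFrame:
    """Attach a ``class_id`` column by classifying each event's ICD code."""
    ev = events.copy()
    keys = ev[["code", "icd_version", "dialect"]].astype(
        {"icd_version": int}).itertuples(index=False)
    cache: dict[tuple, str] = {}
    out = []
    for code, version, dialect in keys:
        k = (code, version, dialect)
        if k not in cache:
            cache[k] = taxonomy.classify(IcdCode(code, int(version), dialect)).class_id
        out.append(cache[k])
    ev["class_id"] = out
    return ev


# -- denominators ---------------------------------------------------------

def _denominators(spans: pd.DataFrame, dates: pd.DatetimeIndex,
                  coarse: bool) -> dict[tuple[str, str], np.ndarray]:
    """Active-enrollee counts per day for every (sex, age_group).

    Age changes only at calendar-year boundaries, so the day range is cut by
    year and each span contributes +1/-1 difference updates to the groups its
    age falls in that year.
    """
    n = len(dates)
    groups = AGE_GROUPS_COARSE if coarse else AGE_GROUPS_FINE
    denom = {(s, g): np.zeros(n + 1) for s in SEXES for g in groups}
    start = pd.to_datetime(spans["start"]).values.astype("datetime64[D]")
    end = pd.to_datetime(spans["end"]).values.astype("datetime64[D]")
    d0 = dates[0].to_datetime64().astype("datetime64[D]")
    si = (start - d0).astype(int)
    ei = (end - d0).astype(int)
    by = spans["birth_year"].to_numpy(int)
    sex = spans["sex"].to_numpy(str)
    for year in range(dates[0].year, dates[-1].year + 1):
        y0 = max((np.datetime64(f"{year}-01-01") - d0).astype(int), 0)
        y1 = min((np.datetime64(f"{year}-12-31") - d0).astype(int), n - 1)
        lo = np.maximum(si, y0)
        hi = np.minimum(ei, y1)
        ok = lo <= hi
        age = year - by
        for g in groups:
            glo, ghi = _BOUNDS[g]
            for s in SEXES:
                m = ok & (sex == s) & (age >= glo) & (age <= ghi)
                if m.any():
                    np.add.at(denom[(s, g)], lo[m], 1)
                    np.add.at(denom[(s, g)], hi[m] + 1, -1)
    return {k: np.cumsum(v[:-1]) for k, v in denom.items()}


# -- main aggregation -----------------------------------------------------

def build_series(events: pd.DataFrame, spans: pd.DataFrame,
                 taxonomy: TaxonomyMap | None,
                 date_range: tuple[dt.date, dt.date],
                 *, coarse_ages: bool = False,
                 setting: str = "all_patient",
                 dedupe_same_day: bool = True) -> tuple[dict[tuple[str, Stratum], DailySeries], dict]:
    """Aggregate events into one :class:`DailySeries` per (class, stratum).

    ``setting="inpatient"`` restricts to events flagged inpatient;
    ``"all_patient"`` uses every event.  Events outside every enrollment span
    of their patient, or outside the date range, are dropped and tallied in
    the returned data-quality report.  Repeat same-day same-class codes for a
    patient count once when ``dedupe_same_day`` (claims repeat codes per
    encounter line).
    """
    if date_range[0] >= date_range[1]:
        raise ValueError("empty date range")
    dates = pd.date_range(date_range[0], date_range[1], freq="D")

    ev = events
    if "class_id" not in ev.columns:
        if taxonomy is None:
            raise ValueError("events lack class_id and no taxonomy was given")
        ev = classify_events(ev, taxonomy)

    report: dict = {"n_events_in": int(len(ev))}
    if setting == "inpatient" and "setting" in ev.columns:
        ev = ev[np.asarray(ev["setting"]) == "inpatient"]
    report["n_events_setting"] = int(len(ev))

    # integer-coded working arrays (memory-lean for multi-million-event inputs)
    day = pd.to_datetime(ev["date"]).values.astype("datetime64[D]")
    d0 = dates[0].to_datetime64().astype("datetime64[D]")
    di = (day - d0).astype(np.int64)
    in_window = (di >= 0) & (di < len(dates))
    report["n_dropped_outside_window"] = int((~in_window).sum())

    cls = ev["class_id"]
    if not isinstance(cls.dtype, pd.CategoricalDtype):
        cls = cls.astype("category")
    class_names = list(cls.cat.categories)
    ci = cls.cat.codes.to_numpy().astype(np.int64)
    pid = ev["patient_id"].to_numpy()

    sp = spans.copy()
    sp["start"] = pd.to_datetime(sp["start"])
    sp["end"] = pd.to_datetime(sp["end"])
    sp_start = (sp["start"].values.astype("datetime64[D]") - d0).astype(np.int64)
    sp_end = (sp["end"].values.astype("datetime64[D]") - d0).astype(np.int64)

    pidx = pd.Index(sp["patient_id"])
    if pidx.is_unique:
        pos = pidx.get_indexer(pid)
        found = pos >= 0
        covered = found & (sp_start[pos] <= di) & (di <= sp_end[pos])
    else:
        # multiple spans per patient: test each event against all of them
        lookup: dict = {}
        for j, p in enumerate(sp["patient_id"]):
            lookup.setdefault(p, []).append(j)
        pos = np.full(len(pid), -1, np.int64)
        covered = np.zeros(len(pid), bool)
        for i, (p, d) in enumerate(zip(pid, di)):
            for j in lookup.get(p, ()):
                if sp_start[j] <= d <= sp_end[j]:
                    pos[i] = j
                    covered[i] = True
                    break
    keep = in_window & covered
    report["n_dropped_outside_spans"] = int((in_window & ~covered).sum())

    span_sex = sp["sex"].to_numpy()[pos]
    rec_sex = (ev["recorded_sex"].to_numpy() if "recorded_sex" in ev.columns
               else span_sex)
    report["n_sex_discordant"] = int((np.asarray(rec_sex)[keep]
                                      != span_sex[keep]).sum())

    birth_year = sp["birth_year"].to_numpy()[pos]
    age = dates.year.to_numpy()[np.clip(di, 0, len(dates) - 1)] - birth_year
    groups = AGE_GROUPS_COARSE if coarse_ages else AGE_GROUPS_FINE
    gi = np.full(len(pid), -1, np.int64)
    for j, g in enumerate(groups):
        lo, hi = _BOUNDS[g]
        gi[(age >= lo) & (age <= hi)] = j
    report["n_dropped_bad_age"] = int((keep & (gi < 0)).sum())
    keep &= gi >= 0

    si = (np.asarray(rec_sex) == "M").astype(np.int64)  # F=0, M=1
    nC, nG, nD = len(class_names), len(groups), len(dates)
    cell = ((ci * 2 + si) * nG + gi) * nD + di
    cell = cell[keep]
    if dedupe_same_day:
        # one count per patient x class x day
        pcodes = pd.factorize(pid)[0].astype(np.int64)
        pkey = pcodes[keep] * (nC * nD) + ci[keep] * nD + di[keep]
        _, first_pos = np.unique(pkey, return_index=True)
        report["n_deduplicated"] = int(len(cell) - len(first_pos))
        cell = cell[np.sort(first_pos)]

    denom = _denominators(sp, dates, coarse_ages)
    totals = np.bincount(cell, minlength=nC * 2 * nG * nD)
    totals = totals.reshape(nC, 2, nG, nD)

    out: dict[tuple[str, Stratum], DailySeries] = {}
    nz = np.argwhere(totals.sum(axis=3) > 0)
    for c, s, g in nz:
        sx, grp = SEXES[s], groups[g]
        stratum = Stratum(sx, grp, setting)
        out[(class_names[c], stratum)] = DailySeries(
            class_names[c], stratum, dates, totals[c, s, g].astype(float),
            denom[(sx, grp)].copy())
    report["n_events_counted"] = int(totals.sum())
    report["n_series"] = len(out)
    return out, report


def first_diagnosis_filter(events: pd.DataFrame, spans: pd.DataFrame) -> pd.DataFrame:
    """Restrict to patients observed since birth; keep each patient's earliest
    event per condition class (same-day ties keep the first in input order)."""
    if "class_id" not in events.columns:
        raise ValueError("events need a class_id column (classify first)")
    osb = spans.groupby("patient_id")["observed_since_birth"].any()
    keep_patients = set(osb[osb].index)
    ev = events[events["patient_id"].isin(keep_patients)].copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev = ev.sort_values("date", kind="stable")
    return ev.groupby(["patient_id", "class_id"], as_index=False, sort=False).head(1)


# -- persistence ----------------------------------------------------------

def series_to_frame(series: Iterable[DailySeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        rows.append(pd.DataFrame({
            "class_id": s.class_id, "sex": s.stratum.sex,
            "age_group": s.stratum.age_group, "setting": s.stratum.setting,
            "date": s.dates, "count": s.counts, "denominator": s.denominators,
        }))
    return pd.concat(rows, ignore_index=True)


def write_series(series: Iterable[DailySeries], path: str | Path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series(path: str | Path) -> dict[tuple[str, Stratum], DailySeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for (cid, sex, g, setting), grp in df.groupby(["class_id", "sex", "age_group", "setting"]):
        grp = grp.sort_values("date")
        stratum = Stratum(sex, g, setting)
        out[(cid, stratum)] = DailySeries(
            cid, stratum, pd.DatetimeIndex(grp["date"]),
            grp["count"].to_numpy(), grp["denominator"].to_numpy())
    return out


def write_quality_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(report), indent=2, default=str))
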