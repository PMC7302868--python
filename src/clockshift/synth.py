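"""Synthetic claims-like cohort generator.

Emulates the statistical structure the DST event study assumes: asynchronous
enrollment and disenrollment, per-condition baseline daily hazards, weekday
multipliers, smooth seasonal variation on the log-hazard, holiday dips, the
23-hour spring and 25-hour autumn shift days, injectable multiplicative DST
effects in chosen strata and seasons, and a small sex-miscoding rate.

Events are drawn per person-day from an inhomogeneous Poisson process with

    rate = baseline x weekday x seasonal x holiday x injected x day_length/24

``expected_counts`` returns the exact per-day mean of this process (no
sampling) and serves as the analytic oracle in calibration tests.  The
enrollment spans are regenerated from a dedicated seed stream, so the oracle
conditions on the same cohort the sampler produced.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calendars import ShiftCalendar
from .incidence import AGE_GROUPS_FINE, SEXES, Stratum, _BOUNDS, _denominators

HazardKey = tuple[str, str, str]  # (class_id, sex or "*", age_group or "*")


@dataclass(frozen=True)
class InjectedEffect:
    """Ground-truth multiplicative DST effect on the hazard.

    Applies to ``class_id`` in the strata matched by ``sex``/``age_group``
    (``None`` = any), on the ``duration_days`` days starting at each
    year's shift date of the given season.
    """

    class_id: str
    season: Literal["spring", "autumn"]
    rr: float
    sex: str | None = None
    age_group: str | None = None
    duration_days: int = 7

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("rr must be positive")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")

    def matches(self, sex: str, age_group: str) -> bool:
        return ((self.sex is None or self.sex == sex)
                and (self.age_group is None or self.age_group == age_group))


@dataclass
class SimulationConfig:
    n_patients: int = 10_000
    study_window: tuple[dt.date, dt.date] = (dt.date(2009, 1, 1), dt.date(2011, 12, 31))
    #: mean enrollment span length in days; churn = 1/mean per-day hazard of
    #: disenrollment. 154 weeks ~ the mean US claims follow-up.
    mean_span_days: float = 154 * 7
    churn: bool = True
    sex_proportions: tuple[float, float] = (0.5, 0.5)  # (F, M)
    birth_year_range: tuple[int, int] = (1925, 2010)
    #: expected diagnoses per person-day, keyed (class_id, sex|*, age_group|*)
    baseline_hazards: dict[HazardKey, float] = field(default_factory=dict)
    #: Mon..Sun; claims volume drops at weekends
    weekday_multipliers: tuple[float, ...] = (1.20, 1.12, 1.08, 1.06, 1.02, 0.42, 0.30)
    seasonal_amplitude: float = 0.15
    seasonal_phase: float = 0.0  # radians; 0 puts the log-hazard peak near Jan 1
    holiday_multiplier: float = 0.5
    dst_effects: list[InjectedEffect] = field(default_factory=list)
    miscoding_rate: float = 0.0052
    inpatient_fraction: float = 0.15
    calendar: ShiftCalendar = field(default_factory=ShiftCalendar)
    #: emitted ICD code per class; defaults to the class_id itself
    class_codes: dict[str, str] = field(default_factory=dict)
    icd_version: int = 10
    dialect: str = "US"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study_window start must precede end")
        if not 0 <= self.miscoding_rate <= 1:
            raise ValueError("miscoding_rate must lie in [0, 1]")
        if len(self.weekday_multipliers) != 7 or any(m <= 0 for m in self.weekday_multipliers):
            raise ValueError("weekday_multipliers must be 7 positive factors")
        if self.holiday_multiplier <= 0:
            raise ValueError("holiday_multiplier must be positive")
        if any(h < 0 for h in self.baseline_hazards.values()):
            raise ValueError("baseline hazards must be non-negative")
        if abs(sum(self.sex_proportions) - 1) > 1e-9:
            raise ValueError("sex_proportions must sum to 1")

    @property
    def class_ids(self) -> list[str]:
        return sorted({k[0] for k in self.baseline_hazards})

    def hazard(self, class_id: str, sex: str, age_group: str) -> float:
        """Baseline hazard with wildcard fallback; 0 when the class carries no
        hazard for the stratum; KeyError when the class is absent entirely."""
        h = self.baseline_hazards
        for key in ((class_id, sex, age_group), (class_id, sex, "*"),
                    (class_id, "*", age_group), (class_id, "*", "*")):
            if key in h:
                return h[key]
        if class_id not in {k[0] for k in h}:
            raise KeyError(f"class {class_id!r} absent from baseline_hazards")
        return 0.0

    def code_for(self, class_id: str) -> str:
        return self.class_codes.get(class_id, class_id)


def flat_hazards(class_ids: Sequence[str], value: float) -> dict[HazardKey, float]:
    """Uniform hazard across all sexes and ages for each listed class."""
    return {(c, "*", "*"): value for c in class_ids}


def codes_from_taxonomy(taxonomy) -> dict[str, str]:
    """A representative (first-interval-start) ICD code per condition class."""
    out: dict[str, str] = {}
    for iv in sorted(taxonomy.entries, key=lambda iv: iv.start):
        out.setdefault(iv.class_id, iv.start)
    return out


# -- deterministic pieces of the generative law ---------------------------

def _dates(config: SimulationConfig) -> pd.DatetimeIndex:
    return pd.date_range(config.study_window[0], config.study_window[1], freq="D")


def _base_factor(config: SimulationConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    """weekday x seasonal x holiday x day-length factor, shared by all strata."""
    wd = np.asarray(config.weekday_multipliers)[dates.weekday]
    doy = dates.dayofyear.to_numpy()
    seasonal = np.exp(config.seasonal_amplitude
                      * np.cos(2 * np.pi * (doy - 1) / 365.25 + config.seasonal_phase))
    hol = np.array([config.holiday_multiplier if config.calendar.is_holiday(d.date())
                    else 1.0 for d in dates])
    dlen = np.array([config.calendar.day_length_hours(d.date()) / 24.0 for d in dates])
    return wd * seasonal * hol * dlen


def _effect_factor(config: SimulationConfig, class_id: str, sex: str,
                   age_group: str, dates: pd.DatetimeIndex) -> np.ndarray:
    f = np.ones(len(dates))
    effects = [e for e in config.dst_effects
               if e.class_id == class_id and e.matches(sex, age_group)]
    if not effects:
        return f
    shifts = config.calendar.shift_dates(range(dates[0].year, dates[-1].year + 1))
    d0 = dates[0].to_datetime64().astype("datetime64[D]")
    for eff in effects:
        for _, season, date in shifts:
            if season != eff.season:
                continue
            i0 = (np.datetime64(date) - d0).astype(int)
            lo, hi = max(i0, 0), min(i0 + eff.duration_days, len(dates))
            if lo < hi:
                f[lo:hi] *= eff.rr
    return f


# -- enrollment spans -----------------------------------------------------

def simulate_spans(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One enrollment span per patient, asynchronous start and churn-driven
    length.  Regenerable from the config seed alone (stream 0)."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    n = config.n_patients
    w0, w1 = config.study_window
    n_days = (w1 - w0).days + 1
    sex = np.where(rng.random(n) < config.sex_proportions[0], "F", "M")
    by0, by1 = config.birth_year_range
    birth_year = rng.integers(by0, by1 + 1, n)
    if config.churn:
        start_off = rng.integers(-int(config.mean_span_days), n_days, n)
        length = rng.geometric(min(1.0, 1.0 / config.mean_span_days), n)
        end_off = start_off + length - 1
    else:
        start_off = np.zeros(n, dtype=int)
        end_off = np.full(n, n_days - 1)
    start = np.array([w0 + dt.timedelta(days=int(o)) for o in start_off])
    end = np.array([w0 + dt.timedelta(days=int(o)) for o in end_off])
    # a span cannot precede the patient's birth
    birth = np.array([dt.date(int(y), 1, 1) for y in birth_year])
    start = np.maximum(start, birth)
    keep = start <= end
    df = pd.DataFrame({
        "patient_id": np.arange(n)[keep],
        "start": start[keep], "end": end[keep],
        "sex": sex[keep], "birth_year": birth_year[keep],
    })
    df["observed_since_birth"] = (
        pd.to_datetime(df["start"]).dt.year.to_numpy() == df["birth_year"].to_numpy())
    return df.reset_index(drop=True)


# -- exact mean (oracle) --------------------------------------------------

def expected_counts(config: SimulationConfig, class_id: str, stratum: Stratum,
                    date_range: tuple[dt.date, dt.date] | None = None,
                    spans: pd.DataFrame | None = None) -> pd.Series:
    """Exact per-day expected event count for one class x stratum.

    Conditions on the enrollment spans (regenerated from the config seed when
    not supplied); this is the mean of the sampling process in
    :func:`simulate_cohort`, with no Monte Carlo error.
    """
    h = config.hazard(class_id, stratum.sex, stratum.age_group)  # KeyError if absent
    if spans is None:
        spans = simulate_spans(config)
    dates = _dates(config)
    coarse = stratum.age_group == "0-20"
    denom = _denominators(spans, dates, coarse)[(stratum.sex, stratum.age_group)]
    mean = (h * _base_factor(config, dates)
            * _effect_factor(config, class_id, stratum.sex, stratum.age_group, dates)
            * denom)
    out = pd.Series(mean, index=dates, name=f"{class_id}|{stratum.label}")
    if date_range is not None:
        out = out.loc[pd.Timestamp(date_range[0]):pd.Timestamp(date_range[1])]
    return out


# -- event sampling -------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (spans, events) from the generative process.

    Deterministic given the config (seed streams: 0 spans, 1 events,
    2 miscoding/setting).  Events carry the true ``class_id``, the emitted
    ICD ``code``, the possibly miscoded ``recorded_sex``, an
    ``is_first_ever`` bookkeeping flag and an inpatient/all-patient
    ``setting`` label.
    """
    spans = simulate_spans(config)
    rng = np.random.default_rng([config.seed, 1])
    dates = _dates(config)
    n_days = len(dates)
    base = _base_factor(config, dates)
    years = dates.year.to_numpy()

    d0 = config.study_window[0]
    start_idx = np.array([(s - d0).days for s in spans["start"]])
    end_idx = np.array([(e - d0).days for e in spans["end"]])
    sex_arr = spans["sex"].to_numpy()
    by_arr = spans["birth_year"].to_numpy()
    pid = spans["patient_id"].to_numpy()

    class_ids = config.class_ids
    ev_pid, ev_day, ev_class = [], [], []
    for s in SEXES:
        for g in AGE_GROUPS_FINE:
            hazards = {c: config.hazard(c, s, g) for c in class_ids}
            if not any(v > 0 for v in hazards.values()):
                continue
            glo, ghi = _BOUNDS[g]
            sex_mask = sex_arr == s
            # membership per day; age changes only at year boundaries
            members, n_act = [], np.zeros(n_days)
            for di in range(n_days):
                age = years[di] - by_arr
                m = (sex_mask & (start_idx <= di) & (end_idx >= di)
                     & (age >= glo) & (age <= ghi))
                idx = np.flatnonzero(m)
                members.append(idx)
                n_act[di] = len(idx)
            for ci, c in enumerate(class_ids):
                if hazards[c] <= 0:
                    continue
                lam = hazards[c] * base * _effect_factor(config, c, s, g, dates) * n_act
                ks = rng.poisson(lam)
                for di in np.flatnonzero(ks):
                    picks = members[di][rng.integers(0, len(members[di]), ks[di])]
                    ev_pid.append(pid[picks])
                    ev_day.append(np.full(ks[di], di, dtype=np.int32))
                    ev_class.append(np.full(ks[di], ci, dtype=np.int32))

    if ev_pid:
        pid_arr = np.concatenate(ev_pid)
        day_arr = np.concatenate(ev_day)
        cls_arr = np.concatenate(ev_class)
    else:
        pid_arr = np.empty(0, int)
        day_arr = cls_arr = np.empty(0, np.int32)
    order = np.lexsort((pid_arr, cls_arr, day_arr))
    pid_arr, day_arr, cls_arr = pid_arr[order], day_arr[order], cls_arr[order]
    events = pd.DataFrame({
        "patient_id": pid_arr,
        "date": dates[day_arr] if len(day_arr) else pd.DatetimeIndex([]),
        "class_id": pd.Categorical.from_codes(cls_arr, categories=class_ids or ["-"]),
    })

    rng2 = np.random.default_rng([config.seed, 2])
    n_ev = len(events)
    pos = pd.Index(spans["patient_id"]).get_indexer(pid_arr)
    true_sex = spans["sex"].to_numpy()[pos] if n_ev else np.empty(0, "U1")
    flip = rng2.random(n_ev) < config.miscoding_rate
    events["recorded_sex"] = np.where(flip, np.where(true_sex == "F", "M", "F"), true_sex)
    events["setting"] = pd.Categorical.from_codes(
        (rng2.random(n_ev) < config.inpatient_fraction).astype(np.int8),
        categories=["outpatient", "inpatient"])
    events["code"] = pd.Categorical.from_codes(
        cls_arr, categories=[config.code_for(c) for c in class_ids] or ["-"])
    events["icd_version"] = config.icd_version
    events["dialect"] = config.dialect
    events["is_first_ever"] = ~events.duplicated(subset=["patient_id", "class_id"])
    return spans, events


# -- persistence ----------------------------------------------------------

def write_cohort(spans: pd.DataFrame, events: pd.DataFrame,
                 config: SimulationConfig, outdir: str | Path) -> None:
    """Write spans.csv, events.csv and a metadata.json echoing seed/config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spans.to_csv(out / "spans.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    meta = dataclasses.asdict(config)
    meta["baseline_hazards"] = {"|".join(k): v for k, v in config.baseline_hazards.items()}
    meta["calendar"] = {"region": config.calendar.region, "rule": config.calendar.rule,
                        "adoption_year": config.calendar.adoption_year,
                        "observes_dst": config.calendar.observes_dst,
                        "n_holidays": len(config.calendar.holidays)}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(indir)
    spans = pd.read_csv(out / "spans.csv", parse_dates=["start", "end"])
    events = pd.read_csv(out / "events.csv", parse_dates=["date"])
    return spans, events
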