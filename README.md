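# clockshift

A phenome-wide event study of the daylight-saving-time (DST) clock change:
from diagnosis-event streams and enrollment spans to shrunken relative-risk
estimates per condition class × sex × age stratum, with negative controls,
automatic signal selection and excess-burden estimation. A synthetic
claims-data generator with injectable ground-truth effects makes every stage
testable without access to proprietary registries.

## Who this is for

Epidemiologists and biostatisticians studying calendar-anchored natural
experiments (clock changes, policy dates, holidays) in administrative health
data — insurance claims or national inpatient registers — where thousands of
condition × stratum series must be screened simultaneously and false
discoveries controlled.

## The method

For each condition class *c* (one of 263 hierarchical, exhaustive ICD
groupings under 31 biological systems) and stratum *s* (sex × age group ×
inpatient/all-patient), the **diagnosis rate** on day *d* is
*r(d) = count(d) / enrollees(d)*. The counterfactual for a day of interest
is the **linear expectation**: the mean rate on the same weekday two weeks
before and two weeks after. The week-level relative risk pooled over years
*y* with shift dates *t_y* is

```
RR = Σ_y O_y / Σ_y E_y ,   O_y = Σ_{k=0..6} (24 / L(t_y + k)) · count(t_y + k)
```

where *L(·)* is the day length (23 h on the spring shift day, 25 h in
autumn, 24 h otherwise) and *E_y* is the expected count from the two
comparator weeks. Comparators falling on listed holidays are replaced by the
same weekday one week further out. Log-scale uncertainty is the delta-method
Poisson variance `se² = 1/O + 1/(C₁+C₂)` with a 0.5 continuity correction
when any count is zero.

Raw log-RRs *yᵢ* are then partially pooled across all condition-strata:

```
yᵢ ~ Normal(θᵢ, sᵢ²),   θᵢ ~ Normal(0, τ²),   τ ~ HalfNormal(0.1)
```

Shrinkage toward RR = 1 encodes the prior that the clock shift leaves most
conditions unaffected and replaces explicit multiple-testing correction.
The frequentist twin reports Wald intervals with a false-coverage-rate (FCR)
adjustment: with *R* of *m* units selected (Benjamini–Hochberg at level
*q*), selected intervals are widened to level *1 − Rq/m*.

Three **negative controls** re-run the identical pipeline where no DST
effect can exist: pseudo-dates 28 days after the spring shift / before the
autumn shift; would-have-been dates in pre-adoption years; and cohorts from
regions that do not observe DST. A condition-stratum is **selected** as a
signal when its credible interval excludes 1 in the real analysis but not in
the paired control; selected signals are ranked by effect size, and excess
burden per shift is `(RR − 1) × expected post-shift-week count`, linearly
scalable to a target population.

## Worked example

```python
import datetime as dt
import clockshift as cs

cal = cs.ShiftCalendar(rule="us", holidays=frozenset())
classes = [f"c{i:02d}" for i in range(20)]
cfg = cs.SimulationConfig(
    n_patients=20_000,
    study_window=(dt.date(2010, 2, 28), dt.date(2010, 5, 1)),
    churn=False, birth_year_range=(1975, 1985),
    baseline_hazards={(c, "F", "21-40"): 0.074 for c in classes},
    weekday_multipliers=(1.0,) * 7, seasonal_amplitude=0.0,
    miscoding_rate=0.0, calendar=cal, seed=42,
    dst_effects=[cs.InjectedEffect(c, "spring", rr=1.1) for c in classes[:5]])

spans, events = cs.simulate_cohort(cfg)
series, _ = cs.build_series(events, spans, None, cfg.study_window)
real = [e for e in cs.estimate_rr(series, cal, [2010], ("spring",))
        if not e.uninformative]
real_fit = cs.fit_hierarchical(real, cs.ShrinkageConfig(seed=1))
_, ctl_fit = cs.run_control(series, cs.ControlSpec(kind="pseudo_date"),
                            cal, [2010], ("spring",),
                            shrinkage_config=cs.ShrinkageConfig(seed=1))
table = cs.select_signals(real_fit, ctl_fit, level=0.99, top_n=30,
                          exclude_ambiguous=False)
up = table.rows[table.rows.direction == "up"]
print(sorted(up.class_id), [round(r, 3) for r in up.point_rr_real])
```

prints

```
['c00', 'c01', 'c02', 'c03', 'c04'] [1.103, 1.102, 1.095, 1.092, 1.091]
```

— the five classes carrying the injected 10% spring effect, and only those,
survive the real-versus-control selection at the 99% credible level. With a
quarter of the units genuinely affected, the estimated population scale τ is
large and shrinkage is mild, so the posterior points sit close to the raw
week-level RRs (≈ 1.10). In sparse-signal regimes (say 10 affected units
out of 200) the same fit pulls effects roughly halfway toward the null —
the price of screening many series at once with no other multiplicity
correction.

A command-line interface mirrors the pipeline stages
(`clockshift simulate | aggregate | estimate | control | select | burden |
report`); each subcommand reads/writes delimited text plus a JSON manifest.

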