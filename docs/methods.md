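# Methods

## Design

The package implements a self-controlled, calendar-anchored event study.
Exposure is the twice-yearly DST clock change; the outcome is the daily
diagnosis rate of a condition class in a sex × age stratum. Because
diagnosis streams carry strong weekday, seasonal and holiday structure, the
counterfactual is built entirely from same-weekday neighbours: the *linear
expectation* averages the rates of the same weekday 14 days before and 14
days after the day of interest, so any confounder that varies smoothly on a
four-week scale cancels to first order. Day-level RRs cover each of the
seven days starting at the shift; the week-level RR collapses the whole
post-shift week (shift Sunday through Saturday by default; a Monday-start
week is a parameter) against the two comparator weeks, which also absorbs the gap between disease onset and the recorded
diagnosis or discharge date. Estimates are pooled across years by summing
observed and expected counts rather than averaging yearly ratios — this is
statistically efficient and avoids zero-count pathologies in rare
conditions.

Two deterministic corrections:

* **Day length.** The spring shift day has 23 hours, the autumn shift day
  25. Observed counts on a shift day are multiplied by `24 / day_length`
  before the ratio, so a constant-hourly-rate process yields RR = 1 exactly
  (verified to machine precision on noise-free series). At pseudo-dates,
  pre-adoption dates and in non-observing regions the calendar reports
  24-hour days and the correction vanishes automatically — the same code
  path serves real analyses and all three negative controls.
* **Holidays.** A comparator falling on a listed holiday is replaced by the
  same weekday one week further out (±21 days, then ±28 if needed), which
  preserves the weekday structure of the design; a `drop` policy (exclude
  the comparator) is available as a config switch. The substitution provably
  leaves a flat series' expectation unchanged.

The uncertainty model is the delta method on independent Poisson counts:
`Var(log RR) = 1/O + 1/(C₁+C₂)` for the two-comparator design, with 0.5
added to every count (point estimate and variance alike) when any count is
zero. For large counts this matches the exact Poisson log-ratio variance;
the null-calibration test checks that the empirical variance of 500 null
log-RRs matches the formula within 20%.

## Hierarchical shrinkage

Per-unit log-RRs are modelled as `yᵢ ~ N(θᵢ, sᵢ²)`, `θᵢ ~ N(μ, τ²)` with
the population mean fixed at 0 (shrinkage toward RR 1). The alternative of
estimating μ with a flat prior is a config flag; it is useful when a whole
analysis might share a common bias, but the default expresses the stronger
prior that the clock shift leaves most conditions unaffected. τ carries a
half-normal prior with scale 0.1 — weakly informative on the log-RR scale,
where plausible population spreads are a few percent; the data dominate
this prior whenever a few hundred units are fitted.

Because the unit layer is conjugate, the sampler is exact rather than
Markovian: τ is drawn from its marginal posterior discretized on an 800-point
grid (μ and θ integrate out analytically), then μ (if estimated) and every
θᵢ from their closed-form Gaussian conditionals. Draws are independent, so
split-R̂ ≈ 1 and ESS ≈ the number of draws by construction; both are still
computed and reported, and a fit with R̂ > 1.01 is flagged rather than
silently returned. A dense quadrature over τ reproduces the sampler's
posterior means to well under 0.01 on toy problems, and the tests keep that
quadrature as an independent oracle.

Consequences of partial pooling worth stating plainly: with μ = 0 every
posterior mean satisfies |E[θᵢ|y]| ≤ |yᵢ| (asserted on every fitted unit),
and when only a small fraction of units carry a true effect, τ is estimated
small and genuine effects are roughly halved on the log scale. Their
credible intervals therefore do *not* cover the unshrunk truth at nominal
rates — that is the designed trade-off that suppresses false discoveries,
and it is why the package always reports the frequentist companion
(unpooled Wald intervals, which do cover) next to the Bayesian summary.

The frequentist twin controls the false coverage rate: units are selected
by Benjamini–Hochberg at level q = 0.05 on two-sided Wald p-values (the
selection rule is injectable), and selected units receive intervals at
level `1 − Rq/m`. Unselected units keep nominal intervals but are never
flagged.

## Negative controls and selection

Three controls re-run the *identical* estimation and shrinkage code:
pseudo-dates (+28 days in spring, −28 in autumn — multiples of 7, so the
shift weekday is preserved), pre-adoption years (rule-generated
would-have-been dates strictly before the adoption year), and non-observing
regions (the real dates applied to a cohort whose days are all 24 h).
Selection requires a unit to be flagged at the chosen credible level in the
real analysis and not flagged in the same direction in the control, drops
classes marked ambiguous (symptom/finding and health-service chapters),
ranks by |log point estimate| and caps each direction at `top_n`
(default 30). "Not significant in control" is evaluated at the same level
as the real analysis. Excess burden per shift is
`(RR − 1) × expected post-shift-week count / n_years`, multiplied by a
linear population-scale factor that is always a config input, never
inferred.

## Condition taxonomy

Codes are normalized (dots stripped, uppercased) and classified by closed
lexical prefix intervals — the natural representation of ICD blocks, and
one on which non-overlap and exhaustiveness are mechanically checkable at
load time. The packaged default map partitions the ICD-10 prefix space
A00–Z99 into 263 condition classes under 31 biological systems following
the WHO chapter/block layout (large chapters such as external causes are
split into several systems; a few oversized blocks are subdivided). It is a
reconstruction from the public WHO structure, not a copy of any particular
register's table; a site-specific mapping file with the same columns can be
dropped in, and code-level crosswalks between ICD versions load from
(source, target) tables. `ambiguous` defaults to true for the
symptoms/findings and health-service chapters, which the headline signal
tables exclude.

## Synthetic cohort generator

The generator emulates exactly the structure the estimator assumes: per
person-day Poisson events with rate

```
baseline(class, sex, age) × weekday × exp(A·cos(2π·doy/365.25 + φ))
  × holiday × (day_length/24) × injected effects
```

with asynchronous enrollment (uniform start, geometric span length),
calendar-year age (a patient crossing an age-group boundary contributes to
both groups' denominators on the appropriate days), optional sex miscoding
(default 0.52%, matching large-claims practice), and an
inpatient/outpatient label per event. `expected_counts` returns the exact
per-day mean of this process conditional on the spans — the spans are
regenerated from a dedicated seed stream, so the oracle and the sampler see
the same cohort, and Monte-Carlo calibration tests need no slack for
denominator noise. Defaults: weekday factors fall to ~0.3–0.4 at weekends,
seasonal amplitude 0.15 on the log scale (winter peak), holiday factor 0.5,
mean span 154 weeks.

What the generator does **not** emulate: disease co-occurrence and
comorbidity, care-seeking feedback, coding-standard drift between ICD
versions, geographic heterogeneity, and hour-of-day structure within the
shift days (the 23/25-hour days enter only as an exposure-time factor).
Passing tests therefore demonstrate that the estimator recovers effects
embedded in data with this statistical skeleton — not robustness to every
artefact of real claims streams.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 20–30 thousand patients over 6–10
week windows, sized so that per-unit standard errors land where the
behaviour under test is identifiable: ~0.09 for null-calibration runs
(500 units), ~0.02 for shrinkage-recovery runs (200 units, 10 injected),
~0.017 for end-to-end selection (200 units, 5 injected at RR 1.1, where
99%-level detection after shrinkage needs se ≲ 0.02). Windows are trimmed
to the days the ±2-week design actually touches. The τ grid spans
[0, max(4·prior scale, 3·sd(y) + max s)] with 800 points; quantile credible
intervals are computed from 4 × 1000 independent draws. Ties in
first-diagnosis filtering keep the first event in input order; same-day
repeat codes for one patient count once by default (claims repeat codes per
encounter line), togglable via `dedupe_same_day`.

## Known limitations

* Swedish-register-style inputs without enrollment spans are supported by
  supplying population-table denominators as spans covering the whole
  window; a native census-denominator path is not implemented.
* The burden figure is a linear extrapolation from the cohort's own
  expected weekly counts; it inherits every bias of the RR point estimate
  and of the scale factor chosen by the user.
* Day-level and week-level RRs share comparator weeks, so their errors are
  correlated; the hierarchical model treats units as independent given τ.
* With μ fixed at 0 the model cannot represent a genuine shift common to
  all conditions; use the estimated-μ variant to probe that possibility.
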