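# Methods

## Recovery models and two-point tailoring

A patient's MMSE trajectory is modeled as `f(t) = a + b·ln(t)`
(logarithmic) or `f(t) = a + b·t` (linear), with `t` in integer days since
stroke onset. Days start at 1: `ln(0)` is undefined, so an assessment on
the day of onset is encoded as day 1. A consequence worth stating is that
for the logarithmic model the intercept `a` equals the modeled score at
day 1, not a hypothetical "score at onset" — the formula, not the informal
gloss, is what the code implements.

Tailoring is strictly two-point: the slope is the score change between the
anchors divided by the change in (transformed) time, and the intercept is
solved from the first anchor. The fitted curve therefore interpolates both
anchors exactly (tested to 1e-9), and no multi-point least-squares
individual fit is offered — the individualization procedure being evaluated
is the two-point one. Negative score changes are allowed; declining
patients are a real phenomenon and the fit must represent them. By default
the first two observations of a series are the anchors; any valid pair can
be passed explicitly.

Two properties follow from concavity of `ln` and are enforced as property
tests: (i) for rising anchors, the linear model's forecast strictly exceeds
the logarithmic model's at every day beyond the second anchor; (ii) a
positive slope gives strictly increasing forecasts for both kinds.

Predictions are kept as real numbers for metric computation (rounding is a
display concern), but are clamped into the instrument range [0, 30] before
being scored: the MMSE ceiling is a property of the test that real
forecasts run into, and patients whose forecast saturates stay in every
metric.

## Synthetic cohorts

No individual-level data are available for this design, so the pipeline is
exercised on simulated cohorts. The generator emulates:

- **Assessment schedule.** Baseline day drawn from a gamma distribution
  parameterized by mean 9.3 / SD 8.1 days (positive, right-skewed — the
  only shape information available is that moment pair), rounded to an
  integer and floored at 1; follow-ups at fixed offsets, default
  +7/+14/+21 days. A first-round-style cohort uses offsets (7, 14).
- **True trajectories.** Logarithmic by default. Intercepts are normal
  (center 19, spread 4); slope magnitudes are lognormal with median 1.8
  points per ln-day and log-scale 0.5, negated for a configurable fraction
  of decliners (default 0.1, motivated by reports that a minority of
  patients decline rather than recover). These individual-level
  distributions are stand-ins — no study reports per-patient parameters —
  so they are loosely calibrated to put the baseline score median near 23
  (IQR ≈ 17–25) and are fully configurable; no acceptance property depends
  on their exact values beyond those targets.
- **Measurement.** Observed score = `round(clamp(f(t) + ε, 0, 30))` with
  ε ~ N(0, noise_sd), default noise_sd = 0.87 points. The default is
  calibrated so the difference of two repeated measurements of the same
  true value (SD 0.87·√2 ≈ 1.23) lies within ±2.4 points about 95% of the
  time, matching published MMSE test-retest spread. On the integer
  observation scale the generator produces, the measured fraction is
  0.953: the two rounding errors are positively correlated and partially
  cancel.

What the simulator does **not** emulate: dropout or missing assessments
(the emulated design analyzes complete cases), covariates (lesion site,
white-matter disease, age, education), practice effects, and any departure
of true recovery from the exact parametric law. Passing tests therefore
show that the pipeline recovers the right answer when the modeling
assumptions hold, and that the log-vs-linear ordering is reproduced under
logarithmic truth — not that real recovery is logarithmic.

## Group time-course analysis

The first-round question — do scores change across assessment occasions —
uses Friedman's test on within-patient ranks (average ranks for ties,
standard tie correction, chi-square reference with occasions−1 df; a grid
with no rank variation returns statistic 0, p = 1) with post-hoc Wilcoxon
signed-rank tests of each later occasion against baseline. The signed-rank
test drops zero differences, average-ranks tied absolute differences,
reports min(W+, W−), and uses the exact null distribution (computed by
convolution over sign assignments, valid with ties) up to 25 informative
pairs, a tie-corrected normal approximation without continuity correction
beyond. All p-values are two-sided; post-hoc p-values are unadjusted by
default with an optional Bonferroni flag, since the emulated analysis plan
names no adjustment. Both tests are verified against brute-force
enumeration oracles on small inputs and against scipy's implementations
where conventions coincide.

The group recovery curve is an OLS fit of score on `ln(day)` or `day`. The
default aggregation regresses per-occasion mean score on per-occasion mean
day (`occasion_summary`); a `pooled` fit over every observation is provided
as a sensitivity variant. The headline choice reflects that a group R²
above 0.9 is a statement about occasion summaries, not about pooled
patient-level scatter, which between-patient heterogeneity would dominate.

## Validation metrics

For each patient with four assessments, both model kinds are tailored from
observations 1–2 and scored at the days of observations 3 and 4 only; a
regression test guards against anchor leakage (including the anchors
inflates percent-correct, since they are interpolated exactly). Metrics per
occasion and kind:

- R² of the OLS regression of actual on predicted score ("conventional
  linear regression" agreement — sign-blind by construction);
- mean ± SD of actual − predicted (unrounded predictions);
- correctness: |actual − predicted| ≤ 3 points, boundary inclusive;
- Pearson chi-square (1 df, no continuity correction) on the 2×2
  correct/incorrect table of logarithmic vs linear counts. The data are
  paired (same patients under both models), so a McNemar variant on the
  discordant pairs is available behind a flag; the unpaired chi-square
  stays the default for fidelity to the emulated analysis plan. A table
  with a zero expected cell (e.g. both models 100% correct on a noise-free
  cohort) carries no evidence and is reported as statistic 0, p = 1.
- If a predictor is constant (everything at the ceiling), the R² for that
  cell is reported as null rather than fabricated.

In the noise-free limit the logarithmic model is exactly identifiable from
a log-truth cohort up to integer rounding, and the 3-point margin is never
exceeded: the forecast error at occasion 3 or 4 is a linear combination of
the two anchor rounding errors with amplification factor
`ln(t₄/t₁)/ln(t₂/t₁)`, which is provably below 3 for every baseline day ≥ 1
under the weekly schedule, so the worst-case error stays under 3 points.
This is the basis of the zero-noise identifiability test.

## Sample size for a correlation

`n = round(((z_{α/2} + z_β)/C)²) + 3` with `C = atanh(r)` the Fisher
z-transform. The squared quotient is rounded to the nearest integer before
adding 3: this is the convention of the published correlation sample-size
tables the calculator mirrors (ceiling would give one more subject at
several entries, e.g. 53 instead of 52 at r = 0.50, α = 0.01, power 0.90).
Quantiles come from the standard normal inverse CDF, not a lookup table.

## Problem sizes and numerical choices

- Simulated cohorts default to 43 patients (a prediction-validation round);
  first-round-style analyses use 57 patients with offsets (7, 14).
  Replicate-based quantities (acceptance script, ordering tests) use 200
  seeded cohorts; distributional checks in the test suite use up to 10,000
  patients or 200,000 draws where a law-of-large-numbers tolerance is
  asserted.
- All randomness flows through `numpy.random.default_rng(seed)`; a cohort
  is a pure function of its config, and the CLI writes sorted-key JSON so
  fixed seeds give byte-identical reports.
- Exact interpolation is asserted at 1e-9; rank-test oracle agreement at
  1e-12 on p-values; moment targets at tolerances derived from standard
  errors at the simulated n.
- Degenerate inputs are first-class: identical anchor days raise a
  dedicated error; all-zero difference vectors return a flagged p = 1;
  series with fewer than four observations are skipped from validation
  with a logged warning (an all-short cohort is an error).

## Known limitations

- The two-point fit propagates anchor measurement error with amplification
  that grows with the forecast horizon; the package quantifies this on
  synthetic data but offers no shrinkage or multi-point alternative by
  design.
- The simulator's parameter distributions are plausible stand-ins, not
  estimates; absolute levels of simulated R² or percent-within-3 should
  not be read as predictions for real cohorts — only orderings and
  identifiability properties are claimed.
- No covariate adjustment, no mixed-effects modeling, no forecasts beyond
  the fourth assessment.
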