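# cogrecov

Predicting early-phase recovery of cognitive function after stroke from two
bedside assessments.

Cognitive impairment is common in the acute stage of stroke, and clinicians
have little to go on when a family asks how much a patient will recover over
the coming weeks. `cogrecov` implements a simple, individualized forecasting
procedure for the Mini-Mental State Examination (MMSE, integer scores 0–30):
two early assessments tailor a recovery curve for that patient, and the curve
forecasts the scores expected at later assessments.

## The models

With `t` the number of days since stroke onset, two candidate recovery laws
are fitted per patient:

- logarithmic: `f(t) = a + b·ln(t)` — fast early gain that plateaus;
- linear: `f(t) = a + b·t`.

Given two anchor assessments `(t₁, s₁)` and `(t₂, s₂)`, the score change
ΔMMSE = `s₂ − s₁` fixes the slope

```
b = ΔMMSE / (ln t₂ − ln t₁)      (logarithmic)
b = ΔMMSE / (t₂ − t₁)            (linear)
```

and `a = s₁ − b·ln(t₁)` (resp. `s₁ − b·t₁`), so the curve passes exactly
through both anchors. Because `ln` is concave, the linear curve tailored to
the same two rising anchors always forecasts *above* the logarithmic one at
later days — linear extrapolation systematically overestimates recovery.

Forecasts are validated against the scores actually obtained at the third
and fourth assessments (the anchors never enter the metrics): R² of the OLS
regression of actual on predicted, the mean ± SD of actual − predicted, and
the fraction of forecasts within 3 points of the truth (a margin justified
by MMSE test-retest differences lying within 2.4 points). A Pearson 2×2
chi-square compares correct/incorrect counts between the two model kinds.

The package also ships the group-level time-course analysis (Friedman test
across assessment occasions, post-hoc Wilcoxon signed-rank versus baseline,
group curve fits with R²), a Fisher-z sample-size calculator for detecting a
correlation, and — because no patient-level data are public — a synthetic
cohort generator that reproduces the structure of such a study (baseline
assessment ≈9 days post-onset with large right skew, weekly follow-ups,
integer scores with ceiling/floor, calibrated test-retest noise).

## Worked example

```
cogrecov simulate --n 43 --seed 11 --out cohort.csv --truth-out truth.json
cogrecov validate --cohort cohort.csv --out report.json --table
```

prints (alongside the machine-readable `report.json`):

```
Profile of predicted recovery (43 patients, threshold 3 points)

                                            occasion 3      occasion 4
Actual MMSE score                           24 (22-28)      25 (22-29)
Predicted MMSE score
  logarithmic                               24 (22-28)      25 (21-28)
  linear                                    25 (22-29)      27 (21-30)
Model fit, R^2
  logarithmic                                     0.92            0.87
  linear                                          0.87            0.73
Difference, actual - predicted (mean+/-SD)
  logarithmic                               -0.0+/-1.6       0.2+/-2.0
  linear                                    -0.4+/-2.0      -0.4+/-3.1
% patients within 3 points
  logarithmic                                     95.3            88.4
  linear                                          90.7            72.1
Log vs linear chi-square (correct/incorrect)
                                        0.72 (p=0.397)  3.59 (p=0.058)
```

Reading the table: each patient's models were tailored from assessments 1–2
only; rows compare their forecasts at assessments 3 and 4 with the scores
actually obtained. The logarithmic model tracks the simulated (logarithmic)
recovery closely — mean difference near zero, most forecasts within the
3-point margin — while the linear model drifts upward by the fourth
assessment (predicted median 27 vs actual 25, only 72% within 3 points):
the concavity-driven overestimation described above.

Sample-size design for such a study:

```
$ cogrecov power --r 0.5 --alpha 0.01 --power 0.9
n = 52
z_alpha/2 = 2.57583
z_beta = 1.28155
C (Fisher z of r) = 0.54931
```

The other subcommands are `cogrecov group` (time-course analysis of a
3-occasion cohort) and `cogrecov simulate --config cfg.yaml` (simulator
driven by a key-value config mirroring `CohortConfig`). Everything is also
available as a library: see `cogrecov.fit_two_point`, `run_validation`,
`analyze_group`, `generate_cohort`, `sample_size_correlation`.

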