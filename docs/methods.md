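# Methods

This note documents the statistical machinery in `traumarisk`, the design
choices made where the design was genuinely open, and what the synthetic
data generator does and does not establish about real registry data.

## Study design implemented

The package implements a two-step temporal validation of logistic
prediction models for early trauma mortality (in-hospital death within 24 h
of the first recorded vital signs) in a multi-hospital cohort:

1. **Updating.** On the earlier ("updating") period, each candidate model's
   coefficients are re-estimated by maximum likelihood while keeping its
   functional form, and a bootstrap linear shrinkage factor is estimated
   and applied.
2. **Validation.** On the later period — truncated at a fixed number of
   events — every updated model is assessed for discrimination (AUROCC,
   sensitivity, specificity), calibration (slope, calibration plots), and
   clinical usefulness (decision curve analysis), with all metrics pooled
   across multiply imputed datasets as median (IQR) and model comparisons
   pooled by median P-value (significant if < 0.05).

## Models

Six model structures are registered (`risk_models`):

| name       | terms                                                           |
|------------|-----------------------------------------------------------------|
| `basic`    | SBP via 4-knot restricted cubic spline + linear GCS             |
| `basic_hr` | as `basic`, plus HR via 4-knot spline                           |
| `kondo`    | linear GCS, indicator age < 60, SBP bands (<60 ref, 60–120, >120)|
| `perel`    | cubic polynomials in age and SBP, quadratic in GCS              |
| `sbp_only` | SBP spline only                                                 |
| `gcs_only` | linear GCS only                                                 |

`kondo` and `perel` ship with their published coefficients as executable
fixtures; `basic`, `basic_hr` and the single-predictor structures cannot be
executed from the literature because their spline knots were never
published, so they must be fitted. Three conventions worth noting:

* The lowest published SBP band is taken as **SBP < 60 mmHg** (the printed
  "SBP < 600" is treated as a typographical error: 600 mmHg is clinically
  impossible and the adjacent band starts at 60). Band boundaries follow
  the printed inclusive form: 60 ≤ SBP ≤ 120, then strictly > 120.
* The three-variable polynomial model is the *re-estimated* form without
  the treatment-indicator term or random intercept of its source trial.
* Predictions on records with a missing covariate raise an error — a
  prediction model must never silently impute at prediction time.

## Restricted cubic splines

For knots `t_1 < … < t_k` the basis is the identity column plus, for each
interior knot `j = 1..k−2`,

    B_j(x) = [ (x−t_j)₊³ − (x−t_{k−1})₊³ (t_k−t_j)/(t_k−t_{k−1})
               + (x−t_k)₊³ (t_{k−1}−t_j)/(t_k−t_{k−1}) ] / (t_k−t_1)²

The division by the squared knot range is the standard scaled restricted
basis; it keeps nonlinear coefficients on a magnitude comparable with the
linear one (relevant when discussing printed coefficient tables whose
scaling convention is unknown). The spline is linear beyond the boundary
knots, so extrapolation to extreme vitals is tame by construction.

Knot placement defaults to **equally spaced percentiles** (20/40/60/80 for
four knots), the literal reading of "four knots placed at equally spaced
percentiles"; the conventional outer scheme (5/35/65/95) is available via
`scheme="outer"`. Knots are computed once — on observed (non-missing)
values of the updating period — and frozen into the model artefact; every
later use (validation, charting) re-uses the stored knots, because a
prediction model must be fully specified before it is validated.

## Maximum-likelihood fitting and shrinkage

Logistic fits go through statsmodels' Newton optimiser with a tolerance of
1e-8 and at most 100 iterations; non-convergence, a single-class outcome,
or coefficients beyond |50| (quasi-separation) raise an explicit error
rather than returning silently huge estimates.

The shrinkage factor for a model fitted on data `D` (n rows) is estimated
by: draw 300 bootstrap resamples of size n with replacement; refit the
model on each; compute each bootstrap model's linear predictor **on the
original `D`**; regress the outcome on that linear predictor (logistic,
with intercept); average the 300 slopes. By maximum-likelihood invariance
the same regression on the original-fit linear predictor returns slope 1
and intercept 0 exactly, which the test-suite uses as the oracle for the
slope-regression sub-step. Resamples that fail to converge are redrawn and
counted; more than 10 % failures aborts with a diagnostic (the cap is a
parameter — scenarios with very few events legitimately need a higher
allowance).

Applying a factor `SF` multiplies the non-intercept coefficients by `SF`
and then **re-estimates the intercept** so that the mean predicted
probability on the updating data equals the observed event rate (this is
exactly the ML intercept given the shrunken linear predictor as offset).
Shrinking the intercept itself would distort the base rate; the literal
variant (every coefficient scaled, no re-estimation) is available via
`literal=True` for completeness.

With multiply imputed updating data, coefficients and shrinkage factors
are estimated **per imputed dataset and averaged**, and the averaged
factor is applied once with the intercept re-estimated on the stacked
datasets. The alternative ordering (stack first, then shrink) is a
one-line change in `pipeline._pooled_model`; the per-dataset route was
chosen because it keeps each bootstrap world internally consistent.

## Multiple imputation

Chained equations with **predictive-mean matching** (PMM, 5 donors,
10 burn-in cycles), implemented directly: each incomplete variable is
regressed on the other predictors (ordinary least squares with a
posterior draw of the coefficients), and each missing cell receives the
observed value of a randomly chosen donor among the 5 closest predicted
means. PMM was chosen over parametric conditionals because it keeps
imputations inside the observed support — GCS stays an integer in 3–15
(enforced by rounding/clipping as well), pressures stay on plausible
positive scales. A hand-rolled sampler (rather than a framework call) was
used so each hospital's chain can be seeded deterministically from
(master seed, dataset index, hospital index): the contract that hospital
A's imputations are bit-identical no matter what happens to hospitals B
and C is then exactly testable.

Default predictor set: SBP, HR, GCS, delay, age, sex, transfer status and
early mortality (the outcome is deliberately part of the imputation
model). An "incomplete observation" is a row missing at least one of SBP,
HR, GCS or age — the variables required to apply all compared models;
delay missingness does not count. `m` = round(100 × worst hospital's
incomplete fraction), floored at 2 when anything is missing, 0 when
nothing is. The pipeline defaults to a reduced `m = 10` for runtime; the
full percentage rule is selected with `StudyDesign(m=None)`.

## Validation metrics

* **AUROCC** is the Mann–Whitney concordance (ties ½), computed by
  scikit-learn and property-tested against a brute-force all-pairs oracle.
  Correlated AUROCCs on the same patients are compared with **DeLong's
  test** (midrank placements, covariance of paired placement values).
  The comparison test is a documented deviation-risk point: the source
  analysis never names its test, and DeLong is the field standard.
* **Calibration slope**: logistic regression of outcome on linear
  predictor. Slopes are compared by a **paired patient-level bootstrap**
  (default 1 000 resamples; 200 in the pipeline default): both slopes are
  refitted per resample and the two-sided P is twice the smaller tail of
  the Δslope distribution at 0. A vectorised two-parameter Newton solver
  performs the per-resample refits; it is cross-checked against the
  statsmodels path in the tests.
* **Sensitivity/specificity** classify positive at p ≥ 0.05 by default,
  aligning with the decision-curve threshold emphasised clinically.
* **Calibration plots**: ten quantile groups of predicted risk (stable
  sort, sizes differing by at most one), with a lowess smooth
  (span 0.75, `delta` = 1 % of the probability range for speed).

## Decision curves

Net benefit `NB = TP/n − (FP/n)·p_t/(1−p_t)` with positivity `p ≥ p_t`
(ties treat). The grid is 0.01–0.50 in steps of 0.01, always containing
0.05. Treat-all follows the closed form `π − (1−π)·p_t/(1−p_t)` (π =
prevalence) and crosses zero at `p_t = π` exactly; both facts are tested
against the counting implementation. Multiply imputed curves are pooled by
the median per (threshold, strategy). The surveys-avoided restatement
`(NB_model − NB_all)(1−p_t)/p_t·100` is reported both as a real number and
integer-truncated, since the rounding convention of the published "45 per
100" figure is not recoverable.

## Synthetic cohort generator

The generator (`synthetic_cohort`) emulates a three-hospital urban trauma
registry so that every stage is testable without patient data. What it
reproduces:

* **Marginals** pinned to published medians/IQRs via two-piece log-normal
  distributions (`x = med·exp(σ_± z)`, σ chosen so the quartiles match
  exactly); GCS as a mixture of a point mass at 15 (weight 0.55) and a
  discrete 3–14 tail giving median 15, IQR 9–15; sex, transfer and injury
  mechanism as categorical draws at the published proportions.
* **A hypotensive tail**: 5 % of patients draw SBP from a low component
  (mean 72, SD 14 on the same latent normal). Median/IQR emulation alone
  leaves essentially no mass below 60 mmHg, which is unrealistic for
  trauma and would leave banded models with an empty reference band.
* **Correlation** among SBP, HR and GCS through a Gaussian copula
  (defaults −0.2 SBP–HR, +0.3 SBP–GCS, −0.1 HR–GCS; published sources give
  no correlations, so these are documented package choices).
* **Outcome truth**: 24-h death is drawn from a logistic model in splined
  SBP (fixed knots 105/115/124/135) and linear GCS (−0.28 per point), with
  coefficients shipped in `data/generating_model.yaml`. The SBP effect
  falls ~0.06 logit/mmHg below 120 and flattens above; the intercept
  (6.565) sets validation-period mortality at 7.0 %. Because outcomes come
  from exactly this model, the calibration slope of the true linear
  predictor is 1 in large samples — the anchor for parameter-recovery and
  decision-curve optimality tests.
* **Missingness**: MCAR, or MAR driven only by always-observed fields
  (hospital, transfer status, mechanism) through a logistic model whose
  intercept is solved so the realised fraction matches the requested rate.
* **Timestamps** uniform over each period's date window, so the temporal
  split and the 200-event stopping rule are exercised.

What it does **not** emulate: injury-severity scores, vitals trajectories,
within-hospital case-mix differences beyond missingness, seasonal arrival
patterns, or informative (MNAR) missingness. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery
under a known truth — not that any particular published coefficient set is
correct for a real population, and published performance numbers computed
on the non-public registry are used only as formatting fixtures, never as
targets.

## Numerical choices and degenerate inputs

* Logit fits: Newton, log-likelihood tolerance 1e-8, ≤ 100 iterations;
  |coef| > 50 treated as separation.
* Knot computation requires ≥ k distinct finite values and strictly
  increasing percentiles, else a degenerate-input error naming the
  variable.
* Quantile grouping breaks prediction ties by stable input order.
* The 200-event rule cuts at the exact arrival timestamp of the cap-th
  death (ties included); day-level granularity (to end of that calendar
  day) is available via a flag, since the boundary convention of the
  original design is not recoverable.
* Every stochastic step (generation, masking, imputation per hospital,
  bootstrap per model per imputed dataset, comparison bootstraps) derives
  its RNG deterministically from the design seed, so a study run is
  byte-reproducible.

## Problem sizes used in the shipped checks

The package's own acceptance checks run the full study at the emulated
scale (n = 4 440; m = 10; 300 bootstrap resamples; six models), recover
generating coefficients at n = 50 000, verify the no-overfitting limit of
the shrinkage factor at n = 100 000, and demonstrate small-sample
shrinkage at 15 events / 6 parameters over 20 seeds. Asymptotic claims use
3-standard-error bands around their Monte-Carlo estimates.

## Known limitations

* The bootstrap comparison of calibration slopes is approximate
  (percentile-at-zero inversion); its type-I error is verified by
  simulation to be near nominal, not derived analytically.
* PMM with a small donor pool can understate between-imputation variance
  in tiny hospitals.
* The published coefficient rows for the two single-predictor structures
  are internally implausible (a positive GCS slope contradicts every other
  model's direction), so those structures are always refitted and the
  printed values never used, even as fixtures.
* Rubin's-rules pooling of coefficient variances is out of scope — pooling
  follows the median/IQR convention of the implemented design throughout.
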