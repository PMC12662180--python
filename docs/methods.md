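# Methods

## The estimand and the analytic model

The pipeline targets the association between longitudinal depression-symptom
exposure and incident probable dementia in panel cohorts with three
symptom-assessment waves. All inference is proportional-hazards: for
participant $i$ with exposure $x_i$ (one of the constructs below) and
covariate vector $z_i$,

$$\lambda_i(t) = \lambda_0(t)\, \exp(\beta x_i + \gamma' z_i),$$

with follow-up time measured from baseline (age at event/censoring minus age
at baseline) and exposure treated as a fixed baseline covariate even though
it is accrued over the first three waves. That treatment mirrors the
standard analytic convention for cumulative exposures in this literature; it
implies the estimates are associational summaries over the full follow-up,
not causal effects of time-varying exposure. A landmark option
(`time_origin="exposure_end"`) restarts the clock at the final exposure wave
for users who prefer to exclude the accrual period, and delayed-entry
age-scale fits are available through `fit_cox(entry_col=...)`; the baseline
origin is the default and is stamped into every output table.

## Exposure constructs and their conventions

- **CumDS** is the trapezoidal integral of the piecewise-linear score curve
  (score-years). Trapezoid additivity — inserting an interpolated time point
  changes nothing — is enforced by test at 1e-10.
- **CumADS** = CumDS / window length; always within the observed score range.
- **Cumulative burden** = CumDS − cutoff × window length. The nonnegative
  class is boundary-*inclusive* (a participant sitting exactly at the cutoff
  throughout counts as exposed). The centering cutoff is the
  outcome-oriented cutoff by default and is an explicit argument, because
  the screening threshold is an equally defensible centering choice.
- **Exposure duration** counts high-score visits (score ≥ cutoff) in a
  two-visit window at 2 years per visit. Which two of the three visits form
  the window is a genuinely open convention; the default is waves 1–2
  (the accrual-period visits), configurable via `duration_window` and
  recorded in run metadata.
- **Slope** is the OLS slope of score on time; the binary coding splits at
  slope ≥ 0.
- **Time-course patterns** classify the signs of $S_2-S_1$ and $S_3-S_2$.
  Zero change maps to "decrease": the four-category scheme has no stable
  class, and non-increase is the conservative assignment, applied
  symmetrically to both transitions.
- **Quartiles** use linear-interpolation percentiles (25/50/75); a value
  equal to a breakpoint joins the lower quartile. Per-quartile medians are
  retained because the trend test scores each participant with their
  quartile's median exposure and refits a single continuous term.
- **VVV**: per-person sample SD (n−1; conventional for few visits), CV only
  where the mean is positive, and VIM = 100·SD/mean^β with β the OLS slope
  of ln SD on ln mean over participants with SD > 0 and mean > 0 (excluded
  participants keep SD/CV but get no VIM; counts are logged). By
  construction the OLS slope of ln VIM on ln mean is zero — a property the
  suite checks at 1e-8. The calibration is per cohort, since the scales'
  ranges differ.

## Outcome-oriented cutpoint

The maximally selected log-rank cutoff evaluates the two-sample log-rank
chi-square at every observed score value whose "score ≥ c" split leaves both
groups with at least 10% of the sample (the standard guard against
degenerate extreme splits; configurable), and returns the maximizer,
breaking ties toward the smaller cutoff for determinism. The log-rank
statistic is implemented directly (O−E accumulation with hypergeometric
variance over distinct event times) and cross-checked against an independent
library implementation at 1e-6. No selection-corrected p-value is computed:
the cutoff is used only to define exposure strata, so the maximal statistic
is never interpreted as a test. By default the search uses baseline scores;
the grid can also be built from the pooled per-visit distribution.

## Algorithmic dementia classification

Education-stratified norms (mean, sample SD per cognitive domain) come from
the baseline wave only, so incident decline cannot contaminate them.
Cognitive impairment is any domain ≤ mean − 1.5 SD (boundary inclusive);
functional impairment is ≥ 1 ADL difficulty; the concurrence rule requires
both, the summary-score rule uses a 0–27 composite ≤ 6. Self-reported
physician diagnosis confers positivity under the "either" basis. Status is
absorbing. Baseline-prevalent cases are excluded before modelling, and the
lagged analysis drops participants first positive at wave 2 to limit
reverse causation from prodromal disease.

## The synthetic-cohort generator

The generator is the ground-truth oracle for every downstream stage. It
emulates: bounded integer symptom trajectories (person intercept + person
slope × time + noise, rounded half-away-from-zero — which keeps marginal
means unbiased near mid-scale — then clipped), independent covariates with
realistic marginal mixes, and event times from an exponential-baseline
proportional-hazards model whose linear predictor applies configured true
log hazard ratios to the participant's *derived* exposures (CumDS, CumADS,
within-cohort per-SD z-scores, duration categories) and covariates.
Continuous terms are mean-centered in the linear predictor; centering is
absorbed by the baseline hazard and leaves hazard ratios untouched.

Scale presets fix the trajectory parameters so that baseline
elevated-symptom prevalence lands near values typical of these instruments
(~18–22% for CES-D-8 at threshold 3, ~25% for EURO-D at 4, ~32–36% for
CES-D-10 at 10), with a baseline hazard of 0.008/year and administrative
censoring at 10.8 years giving ~9–11% cumulative incidence — the
neighbourhood these aging cohorts report. These defaults were chosen once
from the published marginal descriptions and are not tuning knobs.

Cognition/ADL planting works *relative to the realized norms*: baseline
cognitive scores are drawn with education-graded means, norms are computed
from that baseline exactly as the classifier computes them, and events then
receive a memory score 2.5 SD below their stratum mean, a composite ≤ 6 and
one ADL difficulty at and after their event wave, while non-events keep
composites ≥ 7 and zero ADL difficulties. With zero added noise the
classifier is therefore exact by construction (sensitivity = specificity
= 1), which is what makes the classification-bookkeeping tests sharp.
Events occurring after the last assessment wave are recorded at the final
wave, as in cohorts whose last outcome wave ascertains all incident cases.

What the generator does **not** emulate: informative dropout and
missing-data mechanisms (the real pipelines impute; this package is
complete-case by design, with exclusions counted), correlated covariates
(independence suffices for recovery testing and is configurable),
competing mortality, measurement error in covariates, and non-exponential
baseline hazards. Passing recovery tests therefore demonstrates that the
estimation machinery is unbiased and calibrated under the stated model —
not that the published cohort estimates are themselves unconfounded.

## Model ladder and numerics

- M1 unadjusted; M2 + demographics (age, gender, marital status, education,
  residence); M3 + lifestyle and labs (smoking, drinking, CRP, HbA1c, TC,
  HDL-C); M4 + comorbidities (hypertension, diabetes, heart disease,
  stroke). Multi-level factors enter as dummies with the lowest level as
  reference.
- Partial-likelihood maximization uses Efron tie handling via the fitting
  backend. A Breslow flag is not offered because the backend implements
  Efron only; simulated event times are continuous, so ties have
  probability zero and the choice is immaterial there. Requests for
  "breslow" raise rather than silently substituting.
- CIs are Wald on the log scale with z = 1.96; non-convergence raises
  rather than returning a silent fit; constant covariates and zero-event
  samples are rejected up front. No proportional-hazards gate is applied to
  reported fits.
- Restricted cubic splines use the truncated-power natural-spline basis
  with knots at the standard percentile recipes (3 knots: 10/50/90; 4:
  5/35/65/95; 5: 5/27.5/50/72.5/95), scaled by the squared knot span for
  conditioning. Knot count minimizes BIC = −2·log PL + k·ln(events).
  p_overall is the joint Wald test of all spline terms, p_nonlinear of the
  nonlinear terms; curves are reported relative to the cohort median of the
  exposure (the reference anchor is a documented choice, not a convention
  of the literature).
- The pooled per-SD estimate stacks cohorts after within-cohort
  z-standardization (sample SD) and fits one Cox model stratified by cohort
  (separate baseline hazards, common coefficient). This is an
  interpretation of "pooled"; a fixed-effect meta-analysis of per-cohort
  estimates is the main alternative and would differ only at higher-order
  terms.
- Subgroup analyses fit within strata (zero-event strata skipped and
  logged) and test homogeneity by a Wald test on exposure × subgroup
  product terms in the pooled model. Interaction p-values are reported
  unadjusted; no multiplicity correction is applied anywhere beyond
  two-sided α = 0.05.
- Logistic sensitivity fits use complete-case maximum likelihood on the
  ever-dementia indicator with the same covariate ladder; dropped-row
  counts are returned.

## Problem sizes

Recovery experiments use 20 replicates of n = 5000 for per-unit and
duration targets and 3 stacks of four 3000-person cohorts for the pooled
per-SD target (the test suite uses 8 stacks); null-calibration checks use
200 replicates at n = 150–160; spline shape checks 100 replicates at
n = 4000. These sizes put Monte-Carlo error comfortably inside the
tolerances asserted while keeping the whole suite a minutes-scale run on
one CPU.

## Known limitations

Exponential baseline hazards make the lagged analysis exactly unbiased
(memorylessness); under non-exponential baselines the lagged refit is a
left-truncation approximation. The generator's covariate independence means
adjusted and unadjusted fits estimate the same quantity, so the ladder's
M2–M4 rungs exercise numerics rather than confounding control. Dementia
classification here has no noise channel for false positives/negatives
unless explicitly configured, so classifier operating characteristics on
real data cannot be inferred from these tests. Multiple imputation and
competing-risk (subdistribution-hazard) analyses are deliberately out of
scope.
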