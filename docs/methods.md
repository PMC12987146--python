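# Methods

## The simulation model

The cohort simulator generates weekly binary adverse-effect panels for a
synthetic cohort. Its structure is a three-factor probability model with
within-week sequential sampling:

- **Baseline probabilities.** Each of the 11 tracked adverse effects has a
  weekly baseline occurrence probability `p_base` taken from published
  prevalence data for patients on Pembrolizumab plus chemotherapy
  (insomnia 0.21, nausea 0.535, vomiting 0.29, diarrhea 0.43, abdominal
  pain 0.29, cephalea 0.25, hypertension 0.454, pyrexia 0.24, alopecia
  0.54, fatigue 0.585, weight loss 0.27).
- **Susceptibility.** Each patient draws one factor from a Gaussian
  (mean 1.0, sd 0.20) bounded to [0.5, 1.8] that multiplies all of that
  patient's baseline probabilities for the whole simulation. Bounding is
  implemented as resample-until-in-bounds — a true truncated normal —
  because clipping would place point masses at 0.5 and 1.8; a `clip`
  switch is provided for users who want the projected variant.
- **Temporal modifiers.** A per-symptom, per-week multiplier
  `M_temp(s, k)` defaults to 1 for every week (no published temporal
  trend exists). `cycle_ramp_modifiers()` ships an illustrative linear
  ramp, clearly marked as an example, for users exploring
  treatment-cycle dynamics.
- **Correlation rules.** A rule `(trigger, target, b)` additively boosts
  the target's current-week probability by `b` (clamped at 1) the moment
  the trigger fires. The default rule set reads each symptom's
  "correlated with" annotation as trigger → that symptom:
  fatigue→insomnia, nausea→vomiting, diarrhea→abdominal pain,
  {fatigue, nausea, vomiting}→cephalea, fatigue→pyrexia, and
  {nausea, vomiting, diarrhea}→weight loss. No boost magnitude is
  published; the default is b = 0.15 for every rule, configurable per
  rule.
- **Sampling order.** Symptoms are drawn sequentially; a boost can only
  affect targets not yet drawn that week. The default order (fatigue,
  nausea, vomiting, diarrhea, insomnia, abdominal pain, cephalea,
  hypertension, pyrexia, alopecia, weight loss) places every trigger
  before all of its targets so the boosts are effective. The
  order-dependence is inherent to the sequential algorithm and is
  preserved rather than hidden.
- **Boost scope.** Current-week probabilities are rebuilt from the
  clamped baseline product at the start of every week, so boosts never
  persist across weeks.

Randomness uses a single root seed with per-patient `SeedSequence`
substreams: enlarging the cohort leaves earlier patients' trajectories
bit-for-bit unchanged, which makes paired-cohort comparisons (e.g. the
boost-monotonicity test) exact.

Patient profiles also carry a baseline BMI drawn uniformly from
[18, 32]; it feeds the weight-loss detector's threshold choice only and
plays no role in the symptom model.

## The proxy tolerance label

The clinical outcome — "low tolerance to current oncological treatment"
— is an expert judgment (CTCAE grade ≥ 2 effects requiring treatment
modification, dose reduction or delay, suspension, or unplanned
hospitalization). No formula reproduces a clinician's chart review, so
synthetic cohorts are labeled per patient-week by a configurable,
deterministic rule set whose every rule is monotone in the flags:

- concurrent burden: ≥ 5 distinct symptoms in the week;
- sentinel symptom: pyrexia alone (possible febrile neutropenia is an
  oncological emergency and warrants escalation by itself);
- sentinel combinations: {nausea, vomiting, diarrhea} or
  {fatigue, weight loss} present simultaneously;
- persistence: any symptom active 3 consecutive weeks ending now.

These defaults are package choices, not published values. The concurrent
burden threshold was set at 5 because lower values, combined with
weight-loss as a standalone sentinel, label over 90% of the default
cohort positive — implausible against the ~63% positive fraction
reported for the joint real+synthetic dataset that motivated this
design. The shipped defaults give roughly 75–77% positives on the
default cohort, inside the 0.4–0.8 plausibility band the test suite
asserts. Weight loss still contributes through the systemic combination
and the burden count; it does not flip the label on its own over a
6-week horizon.

## Clinical detectors and their thresholds

Published criteria state bands rather than points for several sleep and
weight thresholds. Defaults take the more sensitive end of each band,
consistent with a screening system that favors recall; every value is a
dataclass field and can be overridden.

- **Insomnia.** A night *qualifies* when ≥ 2 of 3 criteria hold:
  duration below baseline by > 20% or < 6 h; efficiency below baseline
  by > 10 points or < 85% absolute; deep and/or REM fraction below
  baseline by > 15% (the stage criterion counts once, as stage
  fragmentation). The weekly flag fires on ≥ 3 consecutive qualifying
  nights or ≥ 4 of 7. The baseline is the mean over the patient's first
  7 monitored nights, which are excluded from flagging.
- **Weight loss.** Percent change Δ% = (baseline − current)/baseline ×
  100, baseline = mean of the first two weekly readings (the single
  reading when only one exists). The cachexia criterion of 5% over 26
  weeks (2% if BMI < 20) rescales linearly to the monitoring horizon:
  5 × 6/26 ≈ 1.15% and 2 × 6/26 ≈ 0.46% over 6 weeks. The flag fires
  when the maximum Δ% over the series reaches the active threshold.
- **Hypertension.** Readings with systolic ≥ 140 **and** diastolic ≥ 90
  mmHg count as exceedances (the "both" reading of the guideline
  wording, with an `either` switch for the conventional definition);
  "multiple measurements" is quantified as ≥ 3 exceedances within the
  week — the smallest plural count robust to a single cuff artifact.
- **Pyrexia.** Fires on skin temperature above 37.8 °C sustained
  ≥ 30 contiguous minutes (rejecting single-sample spikes at the
  ~10-minute cadence), or more than 0.4 °C above the nightly baseline
  for a contiguous span > 2 h. The nightly baseline is the median of
  the first night's samples; contiguous spans never bridge recording
  gaps longer than 4 h, so an evening tail plus next-evening onset
  cannot concatenate into a false episode.
- **Surveys.** Nausea, vomiting, diarrhea, abdominal pain, cephalea,
  alopecia and fatigue are self-reported; the weekly flag is the OR of
  the week's daily responses.

All detectors are pure functions of their inputs and thresholds; streams
too short for a rule raise `InsufficientDataError` rather than returning
a default.

## Signal fixtures

The fixture generators emulate the acquisition schedule of the
monitoring kit (nightly sleep summaries, daily cuff readings, weekly
weights, ~10-minute nocturnal skin temperature, daily surveys) so the
detectors can be tested without device data. They are construction
oracles, not physiology: an active week exceeds the matching detector's
thresholds by a decisive margin (roughly 25% of the threshold magnitude,
severity-scalable for sleep; ≥ 150/95 mmHg cuff readings; 2.5% total
weight decline; fever episodes of 38.2 °C for 1 h or +0.6 °C for 3.5 h),
while an inactive week stays decisively inside them (e.g. skin
temperature within ±0.2 °C of baseline, weight drift within ±0.3%).
Gaussian noise uses small fixed scales (sleep duration 0.25 h, BP 4/3
mmHg, weight 0.1 kg, temperature 0.1 °C), all configurable via
`SignalNoise`.

Consequently the detector round-trip property (≥ 99% flag recovery over
1000 seeded weeks per condition) demonstrates that the rules implement
their definitions, **not** that they would achieve such accuracy on real
wearable data, where deviations cluster near thresholds, baselines
drift, and adherence gaps create missing data the fixtures do not model.

## Feature engineering

Each patient-week row carries 30 model inputs: the 11 raw flags plus 19
engineered features — current-week symptom count; cumulative symptom
load since week 1; 11 per-symptom consecutive-week durations; digestive
(nausea ∧ vomiting ∧ diarrhea), systemic (fatigue ∧ weight loss) and
neurological (cephalea ∧ hypertension) interaction flags; and three
short-horizon dynamics features (previous-week count, week-over-week
count change, longest any-symptom streak to date). The published
description enumerates the load/duration/interaction categories, which
account for 16 engineered features; the three dynamics features are this
package's reconstruction to honor the stated 30-column contract, and the
manifest is exported (`FEATURE_MANIFEST`) so alternative readings can be
swapped in.

## Splitting, scaling and models

Splitting is patient-wise first — 30% of patients (round half away from
zero) become test users, so no individual contributes observations to
both sides — then observation-wise 80/20 within the remaining pool for
train/validation. Under the default 200 × 6 conditions this yields
exactly 672/168/360 observations. MinMax scaling statistics are learned
from training rows only (avoiding leakage; the source procedure does not
specify), constant columns map to 0, and out-of-range values in later
data are left unclipped.

Four families are supported with fixed, sensible defaults (logistic
regression C=1; RBF-kernel SVM C=1; random forest with 300 trees;
gradient boosting with 200 depth-3 trees, learning rate 0.1); any
hyperparameter can be overridden via `model_params`. Probabilistic
families score with `predict_proba`; the margin-based SVM maps its
decision margin through a logistic link onto [0, 1] so the same
threshold semantics apply — a reconstruction, since applying a [0, 1]
threshold to an SVM is otherwise undefined. The alert decision is
strict: ŷ > t_C. Metrics come from the confusion counts, with
zero-denominator ratios reported as NaN rather than 0; AUC-ROC is
trapezoidal integration over score-ranked thresholds.

## Co-occurrence statistics

Prevalence, pairwise Phi and Pearson chi-squared (1 df, no continuity
correction by default, matching the raw p < 0.05 reporting convention;
Bonferroni and continuity switches are provided) are computed over
patient-week observations — consistent with the prevalence denominators
— across all 55 unordered symptom pairs. Tables with a zero marginal
return NaN rather than a value. The identity χ² = n·φ² holds exactly
for the uncorrected statistic and is asserted across random tables.

## Problem sizes and numerical choices

Statistical recovery tests run at the scale their standard errors
require: prevalence recovery uses 2000 patients × 6 weeks (12,000
patient-weeks) against a quadrature oracle of E[clip(p_base·F, 0, 1)]
under the truncated-Gaussian density — the clamp matters in principle
for fatigue (p_base = 0.585, binding when F > 1.709) and the oracle
integrates it exactly; the boost oracle uses 10⁴ replicate weeks against
min(1, p + b); the type-I error check for the co-occurrence reporting
runs 200 null cohorts (boosts off, susceptibility sd 0 so symptoms are
genuinely independent — a nonzero shared susceptibility induces marginal
cross-symptom correlation and is *not* a null); detector round-trips run
1000 seeded weeks per condition. Monte-Carlo assertions use 3-standard-
error bands throughout.

## Known limitations

- The proxy label is a monotone rule over the same flags the features
  encode, so synthetic-cohort classifiers approach perfect scores by
  construction; synthetic evaluations validate the pipeline machinery,
  not clinical performance.
- Binary weekly flags only: no CTCAE severity grades, no
  continuous-valued features, no pharmacokinetics.
- Fixtures generate one weight series per patient, so the weight-loss
  flag round-trips at patient level, not week level — weekly weighing
  cannot encode an arbitrary on/off weekly pattern.
- The simulator's cross-symptom dependence is limited to shared
  susceptibility and one-step additive boosts; real adverse-effect
  dynamics include dose timing, carry-over and treatment changes that
  this model does not represent.
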