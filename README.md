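# oncowatch

Remote-monitoring analytics for oncology treatment tolerance.

Patients on immunotherapy/chemotherapy regimens (e.g. Pembrolizumab plus
chemotherapy) experience adverse effects — nausea, fatigue, insomnia,
hypertension, pyrexia, weight loss and others — that may warrant a
reassessment of the regimen. `oncowatch` implements, end to end, the
analytics layer of a wearable-kit monitoring system for this problem:

1. **Cohort simulator** — a rule-based parametric model of weekly binary
   adverse-effect panels for a synthetic cohort of *N* patients over *W*
   weeks and *M* = 11 symptoms.
2. **Clinical detectors** — deterministic rules turning raw streams
   (nightly sleep summaries, daily blood pressure, weekly weight,
   ~10-minute nocturnal skin temperature, daily surveys) into weekly
   binary condition flags, plus signal-fixture generators to test them.
3. **Proxy labeler** — a configurable rule set standing in for the
   clinician's "low tolerance to current oncological treatment" label.
4. **Feature engineering** — 11 raw flags + 19 longitudinal features =
   a 30-column model input per patient-week.
5. **Alerting models** — patient-wise splitting, MinMax scaling, four
   classifier families (logistic regression, SVM, random forest,
   gradient-boosted trees), metric evaluation and a decision-threshold
   (t_C) sweep.
6. **Co-occurrence statistics** — per-symptom prevalence, pairwise Phi
   correlation and chi-squared independence tests.

## The model

Each patient *i* draws a susceptibility factor *F*<sub>sus</sub>(*i*)
from a Gaussian (μ = 1.0, σ = 0.20) truncated to [0.5, 1.8]. For week
*k* and symptom *s*, the dynamic occurrence probability is

> P′ = P<sub>base</sub>(s) · F<sub>sus</sub>(i) · M<sub>temp</sub>(s, k),  clamped to [0, 1]

Symptoms are drawn sequentially (Bernoulli, u < P) in an order that
places triggers before their targets; when a trigger fires, each
correlation rule (s<sub>trigger</sub> → s<sub>target</sub>, b) boosts
its target's probability by *b* (additively, clamped at 1) for the rest
of that week. Boosts reset weekly. Baseline probabilities and the rule
structure follow published prevalence data for Pembrolizumab plus
chemotherapy; the boost magnitude defaults to b = 0.15 per rule.

The alert decision is binary classification on the 30-column feature
matrix: an alert is issued when the model score ŷ exceeds the decision
threshold t_C (strictly; default 0.5). Performance is reported as
accuracy, precision, recall, specificity, F1 and AUC-ROC, with a sweep
over t_C ∈ {0.1, …, 0.9}.

## Worked example

```sh
oncowatch simulate --seed 5 --out cohort
# wrote 1200 observations for 200 patients to cohort
oncowatch label --cohort cohort/cohort.csv --out labeled.csv
# labeled 1200 observations; positive fraction 0.752
oncowatch features --cohort labeled.csv --out features.csv
# wrote 1200 x 30 feature matrix to features.csv
oncowatch train --features features.csv --model gbm --seed 5 --out report
oncowatch eda --cohort cohort/cohort.csv --out eda
# 15 significant pairs at p < 0.05; outputs in eda
```

The default conditions give 200 patients × 6 weeks = 1200 patient-week
observations; 60 patients (360 observations) are held out as test
users, and the remaining 840 observations split 672/168 into
train/validation. With seed 5 the proxy label marks 75.2% of
observations as low-tolerance, and the trained GBM reports on the
held-out test users:

```json
{"accuracy": 1.0, "precision": 1.0, "recall": 1.0,
 "specificity": 1.0, "f1": 1.0, "auc_roc": 1.0}
```

Near-perfect scores are expected *by construction* here: the proxy
label is a deterministic function of the symptom flags, which the model
sees through the engineered features. These runs validate the
machinery, not clinical performance — see `docs/methods.md` for what
the synthetic results do and do not show.

The same stages are available as a library:

```python
from oncowatch import SimulationConfig, simulate_cohort, label_cohort
from oncowatch import build_feature_matrix, ToleranceAlertClassifier

profiles, cohort = simulate_cohort(SimulationConfig(seed=5))
matrix = build_feature_matrix(label_cohort(cohort))
```

`ToleranceAlertClassifier` and `SymptomFeatureBuilder` follow the
scikit-learn estimator/transformer API (`fit`, `predict`, `transform`,
`get_params`) and compose with sklearn pipelines and model selection.

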