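"""Canonical adverse-effect vocabulary and published simulation parameters.

The eleven adverse effects tracked by the monitoring pipeline, their
baseline weekly occurrence probabilities for patients on Pembrolizumab
plus chemotherapy, and the trigger->target correlation structure between
them. Column order in cohort CSV files is fixed by ``SYMPTOM_COLUMNS``.
"""

from __future__ import annotations

# CSV / panel column order (stable on-disk contract).
SYMPTOM_COLUMNS: tuple[str, ...] = (
    "insomnia",
    "nausea",
    "vomiting",
    "diarrhea",
    "abdominal_pain",
    "cephalea",
    "hypertension",
    "pyrexia",
    "alopecia",
    "fatigue",
    "weight_loss",
)

# Baseline weekly occurrence probabilities (fractions).
DEFAULT_P_BASE: dict[str, float] = {
    "insomnia": 0.21,
    "nausea": 0.535,
    "vomiting": 0.29,
    "diarrhea": 0.43,
    "abdominal_pain": 0.29,
    "cephalea": 0.25,
    "hypertension": 0.454,
    "pyrexia": 0.24,
    "alopecia": 0.54,
    "fatigue": 0.585,
    "weight_loss": 0.27,
}

# Additive within-week probability boost applied by every default rule.
# The published model leaves the boost magnitude open; 0.15 is the
# package default and each rule accepts its own value.
DEFAULT_BOOST: float = 0.15

# (trigger, target) pairs: a symptom listed as "correlated with X" is
# boosted when X fires earlier in the same week.
DEFAULT_CORRELATIONS: tuple[tuple[str, str], ...] = (
    ("fatigue", "insomnia"),
    ("nausea", "vomiting"),
    ("diarrhea", "abdominal_pain"),
    ("fatigue", "cephalea"),
    ("nausea", "cephalea"),
    ("vomiting", "cephalea"),
    ("fatigue", "pyrexia"),
    ("nausea", "weight_loss"),
    ("vomiting", "weight_loss"),
    ("diarrhea", "weight_loss"),
)

# Within-week sampling order: every trigger precedes all of its targets,
# so same-week boosts can act on symptoms not yet drawn.
DEFAULT_SAMPLING_ORDER: tuple[str, ...] = (
    "fatigue",
    "nausea",
    "vomiting",
    "diarrhea",
    "insomnia",
    "abdominal_pain",
    "cephalea",
    "hypertension",
    "pyrexia",
    "alopecia",
    "weight_loss",
)

#: Symptoms whose weekly flag comes from the daily self-report survey
#: rather than a physiological detector.
SURVEY_SYMPTOMS: tuple[str, ...] = (
    "nausea",
    "vomiting",
    "diarrhea",
    "abdominal_pain",
    "cephalea",
    "alopecia",
    "fatigue",
)
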