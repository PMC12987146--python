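"""Proxy labeling of low treatment tolerance from weekly symptom panels.

In the clinic the "low tolerance to current oncological treatment" label
is an expert judgment (CTCAE grade >= 2 adverse effects requiring
treatment modification, dose reduction or delay, suspension, or
unplanned hospitalization).  That judgment is not computable from binary
flags, so synthetic cohorts are labeled by a configurable deterministic
rule set (:class:`~oncowatch.config.LabelRuleConfig`) that fires on
symptom-burden patterns tracking those criteria.  Labels attach per
observation (patient-week).

Every rule is monotone in the symptom flags: adding a symptom to a week
can only turn the label on, never off.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

from .config import LabelRuleConfig

LABEL_COLUMN = "low_tolerance"


def _validate_names(rules: LabelRuleConfig, known: set[str]) -> None:
    referenced = set(rules.sentinel_symptoms)
    for combo in rules.sentinel_combinations:
        referenced |= set(combo)
    unknown = referenced - known
    if unknown:
        raise ValueError(f"label rules reference unknown symptoms: {sorted(unknown)}")


def label_observation(
    week_flags: Mapping[str, int],
    patient_history: Sequence[Mapping[str, int]],
    rules: LabelRuleConfig,
) -> int:
    """Label one patient-week; ``patient_history`` holds prior weeks, oldest first.

    The label is 1 iff any configured rule fires:

    * concurrent burden — at least ``min_concurrent_symptoms`` flags set
      this week;
    * sentinel symptom — any single symptom from ``sentinel_symptoms``
      present;
    * sentinel combination — all members of any configured set present
      simultaneously;
    * persistence — some symptom active for ``persistence_weeks``
      consecutive weeks ending at the current week.
    """
    _validate_names(rules, set(week_flags))

    if sum(week_flags.values()) >= rules.min_concurrent_symptoms:
        return 1
    if any(week_flags.get(s, 0) for s in rules.sentinel_symptoms):
        return 1
    for combo in rules.sentinel_combinations:
        if all(week_flags.get(s, 0) for s in combo):
            return 1
    if rules.persistence_weeks <= len(patient_history) + 1:
        recent = list(patient_history[-(rules.persistence_weeks - 1):]) + [week_flags]
        for symptom, active in week_flags.items():
            if active and all(wk.get(symptom, 0) for wk in recent):
                return 1
    return 0


def label_cohort(cohort: pd.DataFrame, rules: LabelRuleConfig | None = None) -> pd.DataFrame:
    """Append a ``low_tolerance`` column to a weekly cohort panel.

    ``cohort`` must carry ``patient_id``, ``week`` and one binary column
    per symptom (any other columns are preserved).
    """
    rules = rules if rules is not None else LabelRuleConfig()
    symptom_cols = [c for c in cohort.columns if c not in ("patient_id", "week", LABEL_COLUMN)]
    out = cohort.sort_values(["patient_id", "week"]).reset_index(drop=True).copy()

    labels = []
    history: list[Mapping[str, int]] = []
    last_pid = None
    for row in out.itertuples(index=False):
        d = row._asdict()
        if d["patient_id"] != last_pid:
            history = []
            last_pid = d["patient_id"]
        flags = {c: int(d[c]) for c in symptom_cols}
        labels.append(label_observation(flags, history, rules))
        history.append(flags)
    out[LABEL_COLUMN] = labels
    return out
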