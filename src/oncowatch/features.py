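"""Feature engineering: weekly symptom flags -> 30-column model input.

From the 11 raw weekly flags, 19 longitudinal features are derived per
patient-week: symptom-load counts, per-symptom consecutive-week
durations, clinically motivated interaction flags, and short-horizon
dynamics.  The full manifest is ``FEATURE_MANIFEST`` (length 30).

The published feature set enumerates the load, duration and interaction
categories, which account for 16 of the 19 engineered features; the
remaining three here (previous-week count, week-over-week count change,
longest any-symptom streak) are this package's reconstruction and the
manifest is configurable so alternative readings can be swapped in.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .symptoms import SYMPTOM_COLUMNS

__all__ = [
    "FEATURE_MANIFEST",
    "INTERACTION_MEMBERS",
    "weekly_symptom_count",
    "cumulative_symptom_load",
    "symptom_duration",
    "interaction_flags",
    "build_feature_matrix",
    "SymptomFeatureBuilder",
]

INTERACTION_MEMBERS: dict[str, tuple[str, ...]] = {
    "interaction_digestive": ("nausea", "vomiting", "diarrhea"),
    "interaction_systemic": ("fatigue", "weight_loss"),
    "interaction_neurological": ("cephalea", "hypertension"),
}

FEATURE_MANIFEST: tuple[str, ...] = (
    *SYMPTOM_COLUMNS,
    "symptom_count",
    "cumulative_load",
    *(f"duration_{s}" for s in SYMPTOM_COLUMNS),
    *INTERACTION_MEMBERS,
    "prev_week_count",
    "count_change",
    "longest_streak",
)
assert len(FEATURE_MANIFEST) == 30


def weekly_symptom_count(week_flags: Mapping[str, int] | Sequence[int]) -> int:
    """Number of distinct symptoms present in the current week."""
    values = week_flags.values() if isinstance(week_flags, Mapping) else week_flags
    return int(sum(values))


def cumulative_symptom_load(history: Sequence[Mapping[str, int] | Sequence[int]]) -> int:
    """Total symptom reports from week 1 through the current week
    (``history`` includes the current week, oldest first)."""
    return int(sum(weekly_symptom_count(week) for week in history))


def symptom_duration(symptom: str, history: Sequence[Mapping[str, int]]) -> int:
    """Consecutive weeks the symptom has been active, ending at the
    current week (0 if currently inactive)."""
    run = 0
    for week in reversed(history):
        if week.get(symptom, 0):
            run += 1
        else:
            break
    return run


def interaction_flags(week_flags: Mapping[str, int]) -> dict[str, int]:
    """Binary co-occurrence flags for the digestive, systemic and
    neurological symptom clusters (AND of each cluster's members)."""
    return {
        name: int(all(week_flags.get(m, 0) for m in members))
        for name, members in INTERACTION_MEMBERS.items()
    }


def build_feature_matrix(cohort: pd.DataFrame, symptoms: Sequence[str] = SYMPTOM_COLUMNS) -> pd.DataFrame:
    """Assemble the 30-column feature matrix from a weekly cohort panel.

    ``cohort`` must carry ``patient_id``, ``week`` and the binary
    symptom columns; any label column is carried through untouched.
    Rows are keyed by (patient_id, week).
    """
    if cohort.duplicated(subset=["patient_id", "week"]).any():
        raise ValueError("duplicate (patient_id, week) keys in cohort")
    df = cohort.sort_values(["patient_id", "week"]).reset_index(drop=True)
    flags = df[list(symptoms)].to_numpy(dtype=int)
    pid = df["patient_id"].to_numpy()

    n = len(df)
    counts = flags.sum(axis=1)
    cumload = np.zeros(n, dtype=int)
    durations = np.zeros((n, len(symptoms)), dtype=int)
    prev_count = np.zeros(n, dtype=int)
    longest = np.zeros(n, dtype=int)

    any_run = 0
    best_run = 0
    for i in range(n):
        first = i == 0 or pid[i] != pid[i - 1]
        if first:
            cumload[i] = counts[i]
            durations[i] = flags[i]
            prev_count[i] = 0
            any_run = int(counts[i] > 0)
            best_run = any_run
        else:
            cumload[i] = cumload[i - 1] + counts[i]
            durations[i] = np.where(flags[i] == 1, durations[i - 1] + 1, 0)
            prev_count[i] = counts[i - 1]
            any_run = any_run + 1 if counts[i] > 0 else 0
            best_run = max(best_run, any_run)
        longest[i] = best_run

    out = pd.DataFrame({"patient_id": pid, "week": df["week"].to_numpy()})
    for j, s in enumerate(symptoms):
        out[s] = flags[:, j]
    out["symptom_count"] = counts
    out["cumulative_load"] = cumload
    for j, s in enumerate(symptoms):
        out[f"duration_{s}"] = durations[:, j]
    for name, members in INTERACTION_MEMBERS.items():
        out[name] = df[list(members)].all(axis=1).astype(int)
    out["prev_week_count"] = prev_count
    out["count_change"] = counts - prev_count
    out["longest_streak"] = longest

    for col in df.columns:
        if col not in out.columns:  # carry labels / extras through
            out[col] = df[col].to_numpy()
    return out


class SymptomFeatureBuilder(TransformerMixin, BaseEstimator):
    """Stateless transformer wrapping :func:`build_feature_matrix`.

    Fits nothing; exists so the feature step composes with sklearn
    pipelines and parameter search.
    """

    def __init__(self, symptoms: Sequence[str] = SYMPTOM_COLUMNS):
        self.symptoms = symptoms

    def fit(self, X: pd.DataFrame, y=None) -> "SymptomFeatureBuilder":
        missing = set(self.symptoms) - set(X.columns)
        if missing:
            raise ValueError(f"cohort is missing symptom columns: {sorted(missing)}")
        self.feature_names_ = list(FEATURE_MANIFEST)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return build_feature_matrix(X, symptoms=self.symptoms)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_MANIFEST, dtype=object)
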