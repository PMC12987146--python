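"""Alerting stage: splitting, scaling, classifier training and evaluation.

The deployment question — should a reassessment alert be issued for this
patient-week? — is a binary classification problem over the 30-column
feature matrix.  Splitting is patient-wise first (30% of patients held
out as test users, so no individual contributes observations to both
sides), then observation-wise 80/20 within the remaining pool for
train/validation.  Features are MinMax-scaled with statistics learned
from the training rows only.  Four classifier families are supported
(logistic regression, SVM, random forest, gradient-boosted trees), each
exposing a score in [0, 1] so a decision threshold t_C can be swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve, auc as _trapezoid_auc
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SplitSpec",
    "split_patients",
    "split_observations",
    "ScalerState",
    "fit_scaler",
    "apply_scaler",
    "ToleranceAlertClassifier",
    "classify",
    "EvalReport",
    "evaluate",
    "threshold_sweep",
    "DEFAULT_THRESHOLD_GRID",
]

MODEL_FAMILIES = ("logistic", "svm", "random_forest", "gbm")
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass(frozen=True)
class SplitSpec:
    """Patient-wise then observation-wise split fractions."""

    test_user_fraction: float = 0.30
    train_obs_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.test_user_fraction, self.train_obs_fraction):
            if not 0 < frac < 1:
                raise ValueError(f"fraction {frac} must lie in (0, 1)")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_patients(patient_ids: pd.Series | np.ndarray, spec: SplitSpec) -> tuple[list, list]:
    """Partition distinct patients into (test, pool) sets.

    ``round(test_user_fraction * n_patients)`` patients (half away from
    zero) go to test; the split is deterministic for a given seed.
    """
    unique = np.unique(np.asarray(patient_ids))
    n_test = _round_half_away(spec.test_user_fraction * len(unique))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(unique))
    test = sorted(unique[perm[:n_test]].tolist())
    pool = sorted(unique[perm[n_test:]].tolist())
    return test, pool


def split_observations(pool: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-level random split of the pool into (train, validation)."""
    if len(pool) == 0:
        raise ValueError("cannot split an empty observation pool")
    n_train = _round_half_away(spec.train_obs_fraction * len(pool))
    rng = np.random.default_rng(spec.seed + 1)
    perm = rng.permutation(len(pool))
    train = pool.iloc[np.sort(perm[:n_train])]
    valid = pool.iloc[np.sort(perm[n_train:])]
    return train, valid


@dataclass
class ScalerState:
    """Learned per-feature min/max (wraps a fitted sklearn MinMaxScaler)."""

    columns: list[str]
    scaler: MinMaxScaler = field(repr=False)

    @property
    def data_min(self) -> np.ndarray:
        return self.scaler.data_min_

    @property
    def data_max(self) -> np.ndarray:
        return self.scaler.data_max_


def fit_scaler(train: pd.DataFrame, columns: list[str] | None = None) -> ScalerState:
    """Learn MinMax statistics from training rows only.

    Constant columns map to 0; data scaled later may fall outside [0, 1]
    and is deliberately left unclipped.
    """
    cols = columns if columns is not None else list(train.columns)
    scaler = MinMaxScaler(clip=False).fit(train[cols].to_numpy(dtype=float))
    return ScalerState(columns=cols, scaler=scaler)


def apply_scaler(state: ScalerState, data: pd.DataFrame) -> pd.DataFrame:
    scaled = state.scaler.transform(data[state.columns].to_numpy(dtype=float))
    return pd.DataFrame(scaled, columns=state.columns, index=data.index)


_FAMILY_DEFAULTS: dict[str, dict[str, Any]] = {
    "logistic": {"max_iter": 2000, "C": 1.0},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "random_forest": {"n_estimators": 300, "min_samples_leaf": 2},
    "gbm": {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 3},
}


class ToleranceAlertClassifier(ClassifierMixin, BaseEstimator):
    """Binary low-tolerance alert model over scaled weekly features.

    Parameters
    ----------
    family : one of ``logistic``, ``svm``, ``random_forest``, ``gbm``.
    threshold : decision threshold t_C; an alert is issued when the
        score is strictly greater than ``threshold``.
    model_params : overrides merged into the family's default
        hyperparameters.
    random_state : seed forwarded to the underlying estimator.

    Scores are probabilities for the probabilistic families.  For the
    margin-based SVM the decision margin is mapped through a logistic
    link onto [0, 1] so the same threshold sweep applies.
    """

    def __init__(
        self,
        family: str = "gbm",
        threshold: float = 0.5,
        model_params: dict[str, Any] | None = None,
        random_state: int | None = None,
    ):
        self.family = family
        self.threshold = threshold
        self.model_params = model_params
        self.random_state = random_state

    def _make_estimator(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {MODEL_FAMILIES}")
        params = dict(_FAMILY_DEFAULTS[self.family])
        params.update(self.model_params or {})
        if self.family == "logistic":
            return LogisticRegression(random_state=self.random_state, **params)
        if self.family == "svm":
            return SVC(random_state=self.random_state, **params)
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=self.random_state, **params)
        return GradientBoostingClassifier(random_state=self.random_state, **params)

    def fit(self, X, y) -> "ToleranceAlertClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class; cannot fit an alert model")
        self.classes_ = classes
        self.estimator_ = self._make_estimator().fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_score(self, X) -> np.ndarray:
        """Alert score in [0, 1] per row."""
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if self.family == "svm":
            return expit(self.estimator_.decision_function(X))
        return self.estimator_.predict_proba(X)[:, 1]

    # sklearn-compatible alias so roc_auc_score etc. work directly
    def decision_function(self, X) -> np.ndarray:
        return self.predict_score(X)

    def predict(self, X) -> np.ndarray:
        return classify(self.predict_score(X), self.threshold)


def classify(scores: np.ndarray, t_c: float = 0.5) -> np.ndarray:
    """Binary alert decision: 1 iff score is strictly greater than t_C."""
    return (np.asarray(scores, dtype=float) > t_c).astype(int)


@dataclass
class EvalReport:
    """Confusion counts and the standard binary metrics at one threshold.

    Ratios with a zero denominator are reported as NaN, not 0.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc_roc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict[str, float]:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
        }


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(
    predicted: np.ndarray,
    scores: np.ndarray | None,
    truth: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Standard binary-classification metrics from confusion counts.

    AUC-ROC is trapezoidal integration over score-ranked thresholds and
    requires ``scores``; it is NaN when scores are absent or the truth
    is single-class.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))

    precision = _safe_ratio(tp, tp + fp)
    recall = _safe_ratio(tp, tp + fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0 and not (np.isnan(precision) or np.isnan(recall))
        else float("nan")
    )

    auc_roc = float("nan")
    roc_points: list[tuple[float, float]] = []
    if scores is not None and len(np.unique(truth)) == 2:
        fpr, tpr, _ = roc_curve(truth, np.asarray(scores, dtype=float))
        auc_roc = float(_trapezoid_auc(fpr, tpr))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))

    return EvalReport(
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_safe_ratio(tp + tn, tp + fp + tn + fn),
        precision=precision,
        recall=recall,
        specificity=_safe_ratio(tn, tn + fp),
        f1=f1,
        auc_roc=auc_roc,
        roc_points=roc_points,
    )


def threshold_sweep(
    scores: np.ndarray,
    truth: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
) -> pd.DataFrame:
    """Evaluate the alert decision across a grid of thresholds t_C.

    Returns one row per grid value with the full metric set; recall is
    non-increasing and specificity non-decreasing along the grid.
    """
    rows = [
        evaluate(classify(scores, t), scores, truth, threshold=float(t)).to_dict() for t in grid
    ]
    return pd.DataFrame(rows)
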