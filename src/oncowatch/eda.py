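"""Exploratory statistics over weekly symptom panels.

Per-symptom prevalence, pairwise Phi correlation and Pearson chi-squared
independence tests across all unordered symptom pairs, with raw p < 0.05
significance flagging (no multiple-testing correction by default; a
Bonferroni switch is provided).  Statistics are computed over
patient-week observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "prevalence",
    "phi_coefficient",
    "chi2_independence",
    "cooccurrence_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for two binary variables: a=both, b=first only, c=second only, d=neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_flags(cls, x: np.ndarray, y: np.ndarray) -> "ContingencyTable2x2":
        x = np.asarray(x, dtype=bool)
        y = np.asarray(y, dtype=bool)
        return cls(
            a=int(np.sum(x & y)),
            b=int(np.sum(x & ~y)),
            c=int(np.sum(~x & y)),
            d=int(np.sum(~x & ~y)),
        )


def prevalence(cohort: pd.DataFrame, symptoms: list[str] | None = None) -> pd.Series:
    """Per-symptom prevalence in percent over all observations."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    cols = symptoms if symptoms is not None else [
        c for c in cohort.columns if c not in ("patient_id", "week", "low_tolerance")
    ]
    return cohort[cols].mean() * 100.0


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """Phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)); NaN on zero marginals."""
    a, b, c, d = table.a, table.b, table.c, table.d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return (a * d - b * c) / sqrt(denom)


def chi2_independence(table: ContingencyTable2x2, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on the 2x2 table (1 df).

    Returns (statistic, p-value); degenerate tables with a zero marginal
    yield (NaN, NaN).  Without continuity correction the identity
    chi2 = n * phi^2 holds.
    """
    phi = phi_coefficient(table)
    if np.isnan(phi):
        return float("nan"), float("nan")
    observed = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    stat, p, _, _ = stats.chi2_contingency(observed, correction=correction)
    return float(stat), float(p)


def cooccurrence_report(
    cohort: pd.DataFrame,
    symptoms: list[str] | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
    correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Phi matrix and significant-pair table over all symptom pairs.

    Returns
    -------
    phi_matrix : symmetric DataFrame of Phi coefficients (diagonal 1).
    significant : DataFrame (symptom_1, symptom_2, phi, chi2, p_value)
        for pairs with p below the (optionally Bonferroni-divided)
        significance level, sorted by p-value.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    cols = symptoms if symptoms is not None else [
        c for c in cohort.columns if c not in ("patient_id", "week", "low_tolerance")
    ]
    flags = cohort[cols].to_numpy(dtype=bool)

    phi_matrix = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pairs = list(combinations(range(len(cols)), 2))
    threshold = alpha / len(pairs) if bonferroni else alpha
    rows = []
    for i, j in pairs:
        table = ContingencyTable2x2.from_flags(flags[:, i], flags[:, j])
        phi = phi_coefficient(table)
        chi2, p = chi2_independence(table, correction=correction)
        phi_matrix.iloc[i, j] = phi_matrix.iloc[j, i] = phi
        if not np.isnan(p) and p < threshold:
            rows.append(
                {"symptom_1": cols[i], "symptom_2": cols[j], "phi": phi, "chi2": chi2, "p_value": p}
            )
    significant = pd.DataFrame(rows, columns=["symptom_1", "symptom_2", "phi", "chi2", "p_value"])
    return phi_matrix, significant.sort_values("p_value").reset_index(drop=True)
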