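"""Validated configuration objects for the simulation and labeling stages.

All configs are pydantic models so that structured text files (YAML) can
be loaded and validated before any computation runs.  Defaults encode the
published study conditions: a cohort of N=200 patients followed for W=6
weeks over M=11 adverse effects.
"""

from __future__ import annotations

from typing import Any

import yaml
from pydantic import BaseModel, Field, model_validator

from .symptoms import (
    DEFAULT_BOOST,
    DEFAULT_CORRELATIONS,
    DEFAULT_P_BASE,
    DEFAULT_SAMPLING_ORDER,
    SYMPTOM_COLUMNS,
)


class SusceptibilityParams(BaseModel):
    """Bounded-Gaussian parameters of the per-patient susceptibility factor."""

    mean: float = 1.0
    sd: float = Field(default=0.20, ge=0.0)
    lower: float = 0.5
    upper: float = 1.8
    #: ``truncate`` resamples until the draw falls inside the bounds (a true
    #: truncated normal); ``clip`` projects out-of-bound draws onto the
    #: bounds, creating point masses there.
    method: str = "truncate"

    @model_validator(mode="after")
    def _check_bounds(self) -> "SusceptibilityParams":
        if self.lower >= self.upper:
            raise ValueError(f"lower bound {self.lower} must be < upper bound {self.upper}")
        if self.method not in ("truncate", "clip"):
            raise ValueError(f"unknown bounding method {self.method!r}")
        return self


class SymptomSpec(BaseModel):
    """One adverse effect: its baseline probability and temporal profile."""

    name: str
    p_base: float = Field(ge=0.0, le=1.0)
    #: Week-specific multipliers on ``p_base``; length must equal the
    #: simulated horizon.  All-ones means no temporal trend.
    temporal_modifiers: list[float] | None = None

    @model_validator(mode="after")
    def _check_modifiers(self) -> "SymptomSpec":
        if self.temporal_modifiers is not None:
            if any(m < 0 for m in self.temporal_modifiers):
                raise ValueError("temporal modifiers must be >= 0")
        return self


class CorrelationRule(BaseModel):
    """Within-week trigger->target probability boost."""

    trigger: str
    target: str
    boost: float = Field(default=DEFAULT_BOOST, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_distinct(self) -> "CorrelationRule":
        if self.trigger == self.target:
            raise ValueError(f"rule trigger and target are both {self.trigger!r}")
        return self


class SimulationConfig(BaseModel):
    """Full parameterization of the weekly adverse-effect simulator."""

    n_patients: int = Field(default=200, ge=1)
    n_weeks: int = Field(default=6, ge=1)
    symptoms: list[SymptomSpec] = Field(
        default_factory=lambda: [
            SymptomSpec(name=name, p_base=DEFAULT_P_BASE[name]) for name in SYMPTOM_COLUMNS
        ]
    )
    susceptibility: SusceptibilityParams = Field(default_factory=SusceptibilityParams)
    correlation_rules: list[CorrelationRule] = Field(
        default_factory=lambda: [
            CorrelationRule(trigger=t, target=s) for t, s in DEFAULT_CORRELATIONS
        ]
    )
    sampling_order: list[str] = Field(default_factory=lambda: list(DEFAULT_SAMPLING_ORDER))
    #: Baseline BMI range for generated patient profiles (uniform draw);
    #: consumed by the weight-loss detector, not by the symptom model.
    bmi_range: tuple[float, float] = (18.0, 32.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_consistency(self) -> "SimulationConfig":
        names = [s.name for s in self.symptoms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate symptom names")
        if sorted(self.sampling_order) != sorted(names):
            raise ValueError("sampling_order must be a permutation of the symptom names")
        known = set(names)
        for rule in self.correlation_rules:
            for endpoint in (rule.trigger, rule.target):
                if endpoint not in known:
                    raise ValueError(f"correlation rule references unknown symptom {endpoint!r}")
        for spec in self.symptoms:
            if spec.temporal_modifiers is not None and len(spec.temporal_modifiers) != self.n_weeks:
                raise ValueError(
                    f"temporal_modifiers for {spec.name!r} has length "
                    f"{len(spec.temporal_modifiers)}, expected n_weeks={self.n_weeks}"
                )
        return self

    @property
    def symptom_names(self) -> list[str]:
        return [s.name for s in self.symptoms]

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def cycle_ramp_modifiers(n_weeks: int, low: float = 0.7, high: float = 1.3) -> list[float]:
    """Example temporal profile ramping linearly from ``low`` to ``high``.

    Illustrative only — the default simulation uses a flat all-ones
    profile because no published temporal trend is available.
    """
    if n_weeks == 1:
        return [1.0]
    step = (high - low) / (n_weeks - 1)
    return [low + step * k for k in range(n_weeks)]


class LabelRuleConfig(BaseModel):
    """Rule set for the proxy low-treatment-tolerance label.

    A clinician-annotated label (CTCAE grade >= 2, dose modification,
    hospitalization) is not computable from symptom flags alone; this
    configurable surrogate fires on symptom burden patterns that track
    the clinical criteria.  Defaults are package choices, not published
    values: pyrexia is the only standalone sentinel (possible febrile
    neutropenia warrants escalation on its own), and the concurrent
    burden threshold is calibrated so the default synthetic cohort's
    positive fraction lands near the published joint-dataset figure.
    """

    min_concurrent_symptoms: int = Field(default=5, ge=1)
    sentinel_symptoms: list[str] = Field(default_factory=lambda: ["pyrexia"])
    sentinel_combinations: list[list[str]] = Field(
        default_factory=lambda: [
            ["nausea", "vomiting", "diarrhea"],
            ["fatigue", "weight_loss"],
        ]
    )
    persistence_weeks: int = Field(default=3, ge=1)

    @model_validator(mode="after")
    def _check_combinations(self) -> "LabelRuleConfig":
        for combo in self.sentinel_combinations:
            if not combo:
                raise ValueError("sentinel combinations must be non-empty")
        return self

    @classmethod
    def from_yaml(cls, path: str) -> "LabelRuleConfig":
        with open(path) as fh:
            data: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
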