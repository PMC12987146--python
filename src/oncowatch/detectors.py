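"""Rule-based clinical detectors: raw streams -> weekly binary condition flags.

Each detector is a deterministic pure function of its inputs and a
threshold configuration.  Published criteria give bands rather than
points for several thresholds (sleep duration drop ">20-30%", efficiency
floor "80-85%", stage drop "15-20%", weight loss "1-2%" / "0.5-1%"); the
defaults here take the more sensitive end of each band, consistent with
a screening system that favors recall.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .records import BPReading, SkinTempSample, SleepNight, SurveyResponse, WeightReading

__all__ = [
    "SleepThresholds",
    "WeightThresholds",
    "BPThresholds",
    "TempThresholds",
    "DetectorThresholds",
    "SleepBaseline",
    "sleep_baseline",
    "detect_insomnia",
    "weight_pct_change",
    "scaled_weight_threshold",
    "detect_weight_loss",
    "detect_hypertension",
    "detect_pyrexia",
    "surveys_to_flags",
]


class InsufficientDataError(ValueError):
    """Raised when a stream is too short for the detector's rule."""


@dataclass(frozen=True)
class SleepThresholds:
    duration_drop_frac: float = 0.20  # fractional reduction vs baseline
    absolute_min_hours: float = 6.0
    efficiency_drop_points: float = 10.0  # percentage-point reduction vs baseline
    absolute_min_efficiency: float = 85.0
    stage_drop_frac: float = 0.15  # deep and/or REM fractional reduction
    nights_consecutive: int = 3
    nights_of_seven: int = 4
    baseline_days: int = 7


@dataclass(frozen=True)
class WeightThresholds:
    # Guideline criterion: >5% loss over 26 weeks (>2% if BMI < 20),
    # rescaled linearly to the monitoring horizon.
    reference_pct: float = 5.0
    reference_pct_low_bmi: float = 2.0
    reference_weeks: float = 26.0
    horizon_weeks: float = 6.0
    bmi_cutoff: float = 20.0


@dataclass(frozen=True)
class BPThresholds:
    systolic: float = 140.0  # mmHg
    diastolic: float = 90.0  # mmHg
    min_exceedances: int = 3  # "multiple measurements" within the week
    #: ``both``: systolic AND diastolic must exceed (as published);
    #: ``either``: the usual clinical either/or definition.
    logic: str = "both"


@dataclass(frozen=True)
class TempThresholds:
    fever_abs_c: float = 37.8
    persist_minutes: float = 30.0  # minimum run above the absolute threshold
    rise_delta_c: float = 0.4
    rise_duration_hours: float = 2.0


@dataclass(frozen=True)
class DetectorThresholds:
    sleep: SleepThresholds = field(default_factory=SleepThresholds)
    weight: WeightThresholds = field(default_factory=WeightThresholds)
    bp: BPThresholds = field(default_factory=BPThresholds)
    temp: TempThresholds = field(default_factory=TempThresholds)


@dataclass(frozen=True)
class SleepBaseline:
    duration_h: float
    efficiency_pct: float
    deep_pct: float
    rem_pct: float


def sleep_baseline(nights: Sequence[SleepNight], baseline_days: int = 7) -> SleepBaseline:
    """Per-patient sleep baseline: arithmetic means over the first ``baseline_days`` nights."""
    if len(nights) < baseline_days:
        raise InsufficientDataError(
            f"need >= {baseline_days} nights for a baseline, got {len(nights)}"
        )
    window = nights[:baseline_days]
    return SleepBaseline(
        duration_h=float(np.mean([n.duration_h for n in window])),
        efficiency_pct=float(np.mean([n.efficiency_pct for n in window])),
        deep_pct=float(np.mean([n.deep_pct for n in window])),
        rem_pct=float(np.mean([n.rem_pct for n in window])),
    )


def _night_criteria_count(night: SleepNight, baseline: SleepBaseline, t: SleepThresholds) -> int:
    """How many of the three insomnia criteria this night meets."""
    duration_bad = (
        night.duration_h < baseline.duration_h * (1 - t.duration_drop_frac)
        or night.duration_h < t.absolute_min_hours
    )
    efficiency_bad = (
        night.efficiency_pct < baseline.efficiency_pct - t.efficiency_drop_points
        or night.efficiency_pct < t.absolute_min_efficiency
    )
    # deep and/or REM reduction counts as a single criterion (stage fragmentation)
    stage_bad = (
        night.deep_pct < baseline.deep_pct * (1 - t.stage_drop_frac)
        or night.rem_pct < baseline.rem_pct * (1 - t.stage_drop_frac)
    )
    return int(duration_bad) + int(efficiency_bad) + int(stage_bad)


def detect_insomnia(
    nights: Sequence[SleepNight],
    baseline: SleepBaseline,
    thresholds: SleepThresholds | None = None,
) -> int:
    """Weekly insomnia flag over exactly 7 nights.

    A night *qualifies* when at least two of the three criteria hold
    (duration drop or < 6 h; efficiency drop or below the absolute
    floor; deep/REM stage drop).  The flag is 1 iff qualifying nights
    occur on >= 3 consecutive nights or on >= 4 of the 7.
    """
    t = thresholds or SleepThresholds()
    if baseline is None:
        raise InsufficientDataError("sleep baseline required")
    if len(nights) != 7:
        raise ValueError(f"insomnia is evaluated on 7-night weeks, got {len(nights)}")

    qualifying = [_night_criteria_count(n, baseline, t) >= 2 for n in nights]
    if sum(qualifying) >= t.nights_of_seven:
        return 1
    run = best = 0
    for q in qualifying:
        run = run + 1 if q else 0
        best = max(best, run)
    return int(best >= t.nights_consecutive)


def weight_pct_change(baseline_kg: float, current_kg: float) -> float:
    """Percent weight change from baseline; positive values are loss."""
    if baseline_kg <= 0:
        raise ValueError("baseline weight must be > 0")
    return (baseline_kg - current_kg) / baseline_kg * 100.0


def scaled_weight_threshold(
    reference_pct: float, reference_weeks: float, horizon_weeks: float
) -> float:
    """Linearly rescale a weight-loss criterion to a shorter horizon.

    E.g. the 5%-over-26-weeks cachexia criterion becomes ~1.15% over a
    6-week monitoring window.
    """
    if reference_pct <= 0 or reference_weeks <= 0 or horizon_weeks <= 0:
        raise ValueError("all arguments must be > 0")
    return reference_pct * horizon_weeks / reference_weeks


def detect_weight_loss(
    series: Sequence[WeightReading],
    bmi_baseline: float,
    thresholds: WeightThresholds | None = None,
) -> int:
    """Weekly-series weight-loss flag.

    Baseline = mean of the first two weekly readings.  Flag is 1 iff the
    maximum percent loss over the series reaches the horizon-rescaled
    threshold (the more sensitive low-BMI threshold when baseline
    BMI < 20).
    """
    t = thresholds or WeightThresholds()
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 weight readings")
    ordered = sorted(series, key=lambda r: r.week)
    baseline_kg = float(np.mean([r.weight_kg for r in ordered[:2]]))
    reference = t.reference_pct_low_bmi if bmi_baseline < t.bmi_cutoff else t.reference_pct
    threshold = scaled_weight_threshold(reference, t.reference_weeks, t.horizon_weeks)
    max_loss = max(weight_pct_change(baseline_kg, r.weight_kg) for r in ordered)
    return int(max_loss >= threshold)


def detect_hypertension(
    readings: Sequence[BPReading], thresholds: BPThresholds | None = None
) -> int:
    """Hypertension flag: threshold exceedances across multiple measurements."""
    t = thresholds or BPThresholds()
    if not readings:
        raise InsufficientDataError("no blood-pressure readings")
    if t.logic == "both":
        exceed = [r.systolic >= t.systolic and r.diastolic >= t.diastolic for r in readings]
    elif t.logic == "either":
        exceed = [r.systolic >= t.systolic or r.diastolic >= t.diastolic for r in readings]
    else:
        raise ValueError(f"unknown bp logic {t.logic!r}")
    return int(sum(exceed) >= t.min_exceedances)


def detect_pyrexia(
    samples: Sequence[SkinTempSample], thresholds: TempThresholds | None = None
) -> int:
    """Fever flag from nocturnal skin-temperature samples.

    Fires when temperature persistently exceeds the absolute fever
    threshold (37.8 degC for >= ``persist_minutes``), or stays more than
    ``rise_delta_c`` above the patient's nightly baseline for a
    contiguous span longer than ``rise_duration_hours``.  The nightly
    baseline is the median of the first night's samples (the first
    contiguous recording block).
    """
    t = thresholds or TempThresholds()
    if not samples:
        raise InsufficientDataError("no temperature samples")
    times = np.asarray([s.timestamp_min for s in samples], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("temperature samples must be time-ordered")
    temps = np.asarray([s.temperature_c for s in samples], dtype=float)

    # first night = samples up to the first gap > 4 h (or all samples)
    gaps = np.flatnonzero(np.diff(times) > 240.0)
    first_night_end = (gaps[0] + 1) if gaps.size else len(temps)
    nightly_baseline = float(np.median(temps[:first_night_end]))

    def longest_true_span(mask: np.ndarray) -> float:
        """Longest contiguous time span (minutes) where mask holds, without
        bridging recording gaps > 4 h."""
        best = 0.0
        start = None
        for idx in range(len(mask)):
            if mask[idx] and start is None:
                start = idx
            gap_after = idx + 1 < len(mask) and times[idx + 1] - times[idx] > 240.0
            if start is not None and (not mask[idx] or gap_after or idx == len(mask) - 1):
                end = idx if mask[idx] else idx - 1
                best = max(best, times[end] - times[start])
                start = None
        return best

    if longest_true_span(temps > t.fever_abs_c) >= t.persist_minutes:
        return 1
    rise_minutes = t.rise_duration_hours * 60.0
    if longest_true_span(temps > nightly_baseline + t.rise_delta_c) > rise_minutes:
        return 1
    return 0


def surveys_to_flags(responses: Sequence[SurveyResponse]) -> dict[str, int]:
    """Weekly survey-sourced flags: logical OR across the week's daily responses."""
    if not responses:
        raise InsufficientDataError("no survey responses in the week")
    names = SurveyResponse.flag_fields()
    return {name: int(any(getattr(r, name) for r in responses)) for name in names}
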