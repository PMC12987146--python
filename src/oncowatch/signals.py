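"""Synthetic raw-signal fixtures consistent with weekly symptom flags.

These generators emulate the monitoring kit's acquisition schedule
(nightly sleep summaries, daily blood pressure, weekly weight, ~10-min
nocturnal skin temperature, daily surveys) so the clinical detectors can
be exercised without device data.  They are construction oracles, not
physiological models: an *active* week is built to exceed the matching
detector's thresholds by a decisive margin, an *inactive* week to stay
decisively inside them, so the generating flag is recoverable by the
detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detectors import SleepBaseline
from .records import BPReading, SkinTempSample, SleepNight, SurveyResponse, WeightReading

__all__ = [
    "SignalNoise",
    "DEFAULT_SLEEP_BASELINE",
    "synth_sleep_week",
    "synth_bp_week",
    "synth_weight_series",
    "synth_temp_series",
    "synth_survey_week",
]


@dataclass(frozen=True)
class SignalNoise:
    """Gaussian noise scales for each stream."""

    sleep_duration_h: float = 0.25
    sleep_efficiency_pct: float = 1.0
    sleep_stage_pct: float = 0.8
    bp_systolic: float = 4.0
    bp_diastolic: float = 3.0
    weight_kg: float = 0.1
    temp_c: float = 0.1


DEFAULT_NOISE = SignalNoise()

DEFAULT_SLEEP_BASELINE = SleepBaseline(
    duration_h=7.5, efficiency_pct=92.0, deep_pct=18.0, rem_pct=22.0
)


def synth_sleep_week(
    insomnia_active: bool,
    baseline: SleepBaseline = DEFAULT_SLEEP_BASELINE,
    severity: float = 1.0,
    rng: np.random.Generator | None = None,
    noise: SignalNoise = DEFAULT_NOISE,
    start_date: int = 0,
) -> list[SleepNight]:
    """Seven nightly sleep summaries.

    Active weeks contain 5 nights that each violate at least two
    insomnia criteria by a ``severity``-scaled margin; inactive weeks
    hover around baseline.
    """
    if baseline.duration_h <= 0 or not 0 < baseline.efficiency_pct <= 100:
        raise ValueError("invalid sleep baseline")
    if insomnia_active and severity <= 0:
        raise ValueError("severity must be > 0 for an active week")
    rng = rng if rng is not None else np.random.default_rng()

    margin = min(0.25 * severity, 0.6)
    bad_nights = set(rng.choice(7, size=5, replace=False)) if insomnia_active else set()
    nights = []
    for d in range(7):
        if d in bad_nights:
            # violate duration (both clauses), efficiency (both) and stage
            duration = min(baseline.duration_h * (1 - 0.20), 6.0) * (1 - margin)
            efficiency = min(baseline.efficiency_pct - 10.0, 85.0) * (1 - margin)
            deep = baseline.deep_pct * (1 - 0.15) * (1 - margin)
            rem = baseline.rem_pct * (1 - 0.15) * (1 - margin)
        else:
            duration = baseline.duration_h + rng.normal(0, noise.sleep_duration_h)
            efficiency = baseline.efficiency_pct + rng.normal(0, noise.sleep_efficiency_pct)
            deep = baseline.deep_pct + rng.normal(0, noise.sleep_stage_pct)
            rem = baseline.rem_pct + rng.normal(0, noise.sleep_stage_pct)
        nights.append(
            SleepNight(
                date=start_date + d,
                duration_h=max(duration, 0.0),
                efficiency_pct=float(np.clip(efficiency, 0.0, 100.0)),
                deep_pct=max(deep, 0.0),
                rem_pct=max(rem, 0.0),
            )
        )
    return nights


def synth_bp_week(
    hypertension_active: bool,
    rng: np.random.Generator | None = None,
    noise: SignalNoise = DEFAULT_NOISE,
    start_date: int = 0,
) -> list[BPReading]:
    """Seven daily cuff readings.

    Hypertensive weeks contain 4 readings at or above 150/95 mmHg;
    normotensive weeks stay at or below 130/80 mmHg.
    """
    rng = rng if rng is not None else np.random.default_rng()
    high_days = set(rng.choice(7, size=4, replace=False)) if hypertension_active else set()
    readings = []
    for d in range(7):
        if d in high_days:
            sys = max(160.0 + rng.normal(0, noise.bp_systolic), 150.0)
            dia = max(100.0 + rng.normal(0, noise.bp_diastolic), 95.0)
        else:
            sys = min(118.0 + rng.normal(0, noise.bp_systolic), 130.0)
            dia = min(72.0 + rng.normal(0, noise.bp_diastolic), 80.0)
        hr = 70.0 + rng.normal(0, 5.0)
        readings.append(
            BPReading(date=start_date + d, systolic=sys, diastolic=dia, heart_rate=hr)
        )
    return readings


def synth_weight_series(
    weight_loss_active: bool,
    baseline_kg: float,
    n_weeks: int = 6,
    rng: np.random.Generator | None = None,
    noise: SignalNoise = DEFAULT_NOISE,
) -> list[WeightReading]:
    """Weekly scale readings.

    An active series declines linearly to 2.5% below the starting weight
    by the final week (comfortably past the ~1.15% six-week screening
    threshold); an inactive series drifts within +/-0.3% of baseline.
    """
    if baseline_kg <= 0:
        raise ValueError("baseline weight must be > 0")
    if n_weeks < 1:
        raise ValueError("need n_weeks >= 1")
    rng = rng if rng is not None else np.random.default_rng()

    readings = []
    for k in range(n_weeks):
        if weight_loss_active and n_weeks > 1:
            trend = baseline_kg * (1 - 0.025 * k / (n_weeks - 1))
        else:
            trend = baseline_kg
        w = trend + rng.normal(0, noise.weight_kg)
        if not weight_loss_active:
            w = float(np.clip(w, baseline_kg * 0.997, baseline_kg * 1.003))
        readings.append(WeightReading(week=k + 1, weight_kg=w))
    return readings


def synth_temp_series(
    pyrexia_active: bool,
    rng: np.random.Generator | None = None,
    noise: SignalNoise = DEFAULT_NOISE,
    n_nights: int = 7,
    night_minutes: int = 360,
    cadence_min: int = 10,
) -> list[SkinTempSample]:
    """Nocturnal skin-temperature samples for one week at ~10-min cadence.

    Active weeks embed, on a night after the first, either an absolute
    fever exceedance (>= 38.1 degC for 60 min) or a sustained rise of
    0.6 degC above the nightly baseline lasting 3.5 h with a sub-febrile
    peak; the mode is chosen at random.  Inactive weeks stay within
    +/-0.2 degC of a 36.5-37.0 degC nightly baseline.
    """
    rng = rng if rng is not None else np.random.default_rng()
    base = rng.uniform(36.5, 37.0)

    mode = None
    episode_night = None
    if pyrexia_active:
        if n_nights < 2:
            raise ValueError("need >= 2 nights to embed an episode after the baseline night")
        mode = "absolute" if rng.uniform() < 0.5 else "rise"
        episode_night = int(rng.integers(1, n_nights))

    samples = []
    for night in range(n_nights):
        episode_window: tuple[float, float] | None = None
        if night == episode_night:
            if mode == "absolute":
                ep_start = rng.uniform(60, night_minutes - 120)
                episode_window = (ep_start, ep_start + 60.0)
            else:
                ep_start = rng.uniform(0, night_minutes - 220)
                episode_window = (ep_start, ep_start + 210.0)
        for t in range(0, night_minutes + 1, cadence_min):
            abs_t = night * 1440.0 + t
            if episode_window and episode_window[0] <= t <= episode_window[1]:
                if mode == "absolute":
                    temp = 38.2 + float(np.clip(rng.normal(0, noise.temp_c), -0.1, 0.3))
                else:
                    temp = base + 0.6 + float(np.clip(rng.normal(0, noise.temp_c), -0.05, 0.05))
            else:
                temp = base + float(np.clip(rng.normal(0, noise.temp_c), -0.2, 0.2))
            samples.append(SkinTempSample(timestamp_min=abs_t, temperature_c=temp))
    return samples


def synth_survey_week(
    week_flags: dict[str, int],
    rng: np.random.Generator | None = None,
    start_date: int = 0,
) -> list[SurveyResponse]:
    """Seven daily survey responses; a symptom is reported on at least one
    day iff its weekly flag is set."""
    rng = rng if rng is not None else np.random.default_rng()
    names = SurveyResponse.flag_fields()
    daily = {name: np.zeros(7, dtype=bool) for name in names}
    for name in names:
        if week_flags.get(name, 0):
            days = rng.uniform(size=7) < 0.5
            if not days.any():
                days[rng.integers(0, 7)] = True
            daily[name] = days
    return [
        SurveyResponse(date=start_date + d, **{name: bool(daily[name][d]) for name in names})
        for d in range(7)
    ]
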