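"""Raw data records produced by the monitoring kit.

Lightweight validated containers for the per-patient streams: nightly
sleep summaries (smartwatch), daily blood-pressure readings
(tensiometer), weekly weights (smart scale), high-frequency skin
temperature (smartwatch), and daily symptom surveys (mobile app).
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class SleepNight:
    """One night's sleep summary."""

    date: int  # day index within the monitoring period
    duration_h: float
    efficiency_pct: float
    deep_pct: float  # percent of total sleep in deep sleep
    rem_pct: float  # percent of total sleep in REM

    def __post_init__(self) -> None:
        if self.duration_h < 0:
            raise ValueError("sleep duration must be >= 0")
        if not 0 <= self.efficiency_pct <= 100:
            raise ValueError("sleep efficiency must be in [0, 100]")
        if self.deep_pct < 0 or self.rem_pct < 0:
            raise ValueError("stage fractions must be >= 0")


@dataclass(frozen=True)
class BPReading:
    """One cuff measurement."""

    date: int
    systolic: float  # mmHg
    diastolic: float  # mmHg
    heart_rate: float  # bpm

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic > 0:
            raise ValueError("require systolic > diastolic > 0")


@dataclass(frozen=True)
class WeightReading:
    week: int  # 1-based week index
    weight_kg: float

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class SkinTempSample:
    timestamp_min: float  # minutes since start of the monitoring window
    temperature_c: float

    def __post_init__(self) -> None:
        # physiological plausibility guard for skin temperature
        if not 30.0 <= self.temperature_c <= 43.0:
            raise ValueError(f"skin temperature {self.temperature_c} outside 30-43 degC")


@dataclass(frozen=True)
class SurveyResponse:
    """One day's self-reported symptom checklist."""

    date: int
    nausea: bool = False
    vomiting: bool = False
    diarrhea: bool = False
    abdominal_pain: bool = False
    cephalea: bool = False
    alopecia: bool = False
    fatigue: bool = False

    @classmethod
    def flag_fields(cls) -> list[str]:
        return [f.name for f in fields(cls) if f.name != "date"]
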