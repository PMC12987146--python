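"""Clinical detector rules on hand-constructed streams."""

import numpy as np
import pytest

from oncowatch.detectors import (
    BPThresholds,
    InsufficientDataError,
    SleepBaseline,
    detect_hypertension,
    detect_insomnia,
    detect_pyrexia,
    detect_weight_loss,
    scaled_weight_threshold,
    sleep_baseline,
    surveys_to_flags,
    weight_pct_change,
)
from oncowatch.records import BPReading, SkinTempSample, SleepNight, SurveyResponse, WeightReading

BASE = SleepBaseline(duration_h=7.0, efficiency_pct=92.0, deep_pct=18.0, rem_pct=22.0)


def night(duration=7.0, efficiency=92.0, deep=18.0, rem=22.0, date=0):
    return SleepNight(
        date=date, duration_h=duration, efficiency_pct=efficiency, deep_pct=deep, rem_pct=rem
    )


class TestSleepBaseline:
    def test_mean_over_first_seven_nights(self):
        nights = [night(duration=d, date=i) for i, d in enumerate([6, 7, 8, 7, 6, 7, 8])]
        assert sleep_baseline(nights).duration_h == pytest.approx(7.0)

    def test_identical_nights_return_those_values(self):
        base = sleep_baseline([night(date=i) for i in range(7)])
        assert base == BASE

    def test_too_few_nights_rejected(self):
        with pytest.raises(InsufficientDataError):
            sleep_baseline([night(date=i) for i in range(6)])


class TestDetectInsomnia:
    def test_baseline_week_is_negative(self):
        assert detect_insomnia([night(date=i) for i in range(7)], BASE) == 0

    def test_four_of_seven_bad_nights_fire(self):
        # duration < 6 h and efficiency below the absolute floor: two criteria
        bad = night(duration=4.0, efficiency=70.0)
        nights = [bad, night(), bad, night(), bad, night(), bad]
        assert detect_insomnia(nights, BASE) == 1

    def test_three_consecutive_bad_nights_fire(self):
        bad = night(duration=4.0, efficiency=70.0)
        nights = [night(), bad, bad, bad, night(), night(), night()]
        assert detect_insomnia(nights, BASE) == 1

    def test_single_criterion_nights_do_not_fire(self):
        # every night short on duration only: one criterion is not enough
        nights = [night(duration=4.0) for _ in range(7)]
        assert detect_insomnia(nights, BASE) == 0

    def test_missing_baseline_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_insomnia([night() for _ in range(7)], None)


class TestWeightRules:
    @pytest.mark.parametrize(
        "baseline, current, expected",
        [(80.0, 80.0, 0.0), (100.0, 98.85, 1.15), (80.0, 84.0, -5.0)],
    )
    def test_pct_change_hand_values(self, baseline, current, expected):
        assert weight_pct_change(baseline, current) == pytest.approx(expected)

    def test_pct_change_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            weight_pct_change(0.0, 70.0)

    def test_antisymmetry_up_to_scale(self):
        a, b = 82.0, 78.5
        assert weight_pct_change(a, b) == pytest.approx(-weight_pct_change(b, a) * b / a)

    @pytest.mark.parametrize(
        "ref_pct, ref_weeks, horizon, expected",
        [(5.0, 26.0, 6.0, 30 / 26), (2.0, 26.0, 6.0, 12 / 26), (5.0, 26.0, 26.0, 5.0)],
    )
    def test_scaled_threshold(self, ref_pct, ref_weeks, horizon, expected):
        assert scaled_weight_threshold(ref_pct, ref_weeks, horizon) == pytest.approx(expected)

    def test_rescaled_thresholds_round_to_printed_values(self):
        assert round(scaled_weight_threshold(5.0, 26.0, 6.0), 2) == 1.15
        assert round(scaled_weight_threshold(2.0, 26.0, 6.0), 1) == 0.5

    def test_flat_series_negative(self):
        series = [WeightReading(week=k + 1, weight_kg=80.0) for k in range(6)]
        assert detect_weight_loss(series, bmi_baseline=25.0) == 0

    def test_loss_past_threshold_fires(self):
        # 100 -> 98.5 kg: 1.5% >= 1.15% six-week threshold
        weights = [100.0, 100.0, 99.6, 99.2, 98.8, 98.5]
        series = [WeightReading(week=k + 1, weight_kg=w) for k, w in enumerate(weights)]
        assert detect_weight_loss(series, bmi_baseline=25.0) == 1

    def test_low_bmi_uses_sensitive_threshold(self):
        # 0.7% loss: below 1.15% but above the 0.46% low-BMI threshold
        weights = [100.0, 100.0, 99.8, 99.6, 99.4, 99.3]
        series = [WeightReading(week=k + 1, weight_kg=w) for k, w in enumerate(weights)]
        assert detect_weight_loss(series, bmi_baseline=19.0) == 1
        assert detect_weight_loss(series, bmi_baseline=25.0) == 0

    def test_single_reading_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_weight_loss([WeightReading(week=1, weight_kg=80.0)], 25.0)


def bp(sys, dia, date=0):
    return BPReading(date=date, systolic=sys, diastolic=dia, heart_rate=70.0)


class TestDetectHypertension:
    def test_normotensive_week_negative(self):
        assert detect_hypertension([bp(120, 70, d) for d in range(7)]) == 0

    def test_three_exceedances_fire(self):
        readings = [bp(150, 95, 0), bp(120, 70, 1), bp(150, 95, 2), bp(150, 95, 3)]
        assert detect_hypertension(readings) == 1

    def test_systolic_only_exceedance_ignored_under_both_policy(self):
        readings = [bp(150, 85, d) for d in range(7)]
        assert detect_hypertension(readings) == 0
        assert detect_hypertension(readings, BPThresholds(logic="either")) == 1

    def test_two_exceedances_insufficient(self):
        readings = [bp(150, 95, 0), bp(150, 95, 1), bp(120, 70, 2)]
        assert detect_hypertension(readings) == 0

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_hypertension([])


def temp_series(values, cadence=10.0, start=0.0):
    return [
        SkinTempSample(timestamp_min=start + i * cadence, temperature_c=v)
        for i, v in enumerate(values)
    ]


class TestDetectPyrexia:
    def test_flat_series_negative(self):
        assert detect_pyrexia(temp_series([36.8] * 60)) == 0

    def test_sustained_absolute_exceedance_fires(self):
        values = [36.8] * 20 + [38.0] * 7 + [36.8] * 20  # 60 min above 37.8
        assert detect_pyrexia(temp_series(values)) == 1

    def test_momentary_spike_does_not_fire(self):
        values = [36.8] * 20 + [38.5] + [36.8] * 20
        assert detect_pyrexia(temp_series(values)) == 0

    def test_sustained_subfebrile_rise_fires(self):
        # 0.5 degC above the 36.9 nightly baseline for 3 h, peak 37.4 < 37.8
        first_night = [36.9] * 37
        second_night = [36.9] * 5 + [37.4] * 19 + [36.9] * 5
        samples = temp_series(first_night) + temp_series(second_night, start=1440.0)
        assert detect_pyrexia(samples) == 1

    def test_unordered_timestamps_rejected(self):
        samples = temp_series([36.8, 36.8])[::-1]
        with pytest.raises(ValueError, match="time-ordered"):
            detect_pyrexia(samples)

    def test_span_does_not_bridge_recording_gaps(self):
        # 1 h warm at the end of one night plus 1.5 h at the start of the
        # next is not a contiguous > 2 h episode
        night1 = [36.8] * 30 + [37.4] * 7
        night2 = [37.4] * 9 + [36.8] * 28
        samples = temp_series(night1) + temp_series(night2, start=1440.0)
        assert detect_pyrexia(samples) == 0


class TestSurveysToFlags:
    def test_all_false_week(self):
        responses = [SurveyResponse(date=d) for d in range(7)]
        assert sum(surveys_to_flags(responses).values()) == 0

    def test_single_day_report_sets_weekly_flag(self):
        responses = [SurveyResponse(date=0, nausea=True)] + [
            SurveyResponse(date=d) for d in range(1, 7)
        ]
        flags = surveys_to_flags(responses)
        assert flags["nausea"] == 1 and flags["vomiting"] == 0

    def test_idempotent_on_duplicated_days(self):
        responses = [SurveyResponse(date=0, fatigue=True)] * 3
        assert surveys_to_flags(responses) == surveys_to_flags(responses * 2)

    def test_empty_week_rejected(self):
        with pytest.raises(InsufficientDataError):
            surveys_to_flags([])
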