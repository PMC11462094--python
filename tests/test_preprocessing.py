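"""Cleaning rules, Tukey fences, window building, and wear-time summaries."""

import math
import random
from datetime import date, timedelta

import numpy as np
import pytest

from actiphen import (
    ActivityWindow,
    Brand,
    DailyActivityRecord,
    IBDType,
    QuestionnaireResponse,
    build_windows,
    clean_daily_records,
    remove_unrealistic,
    tukey_outlier_filter,
    wear_summary,
)
from actiphen.core import PROMIS_DOMAINS


def _record(day, **metrics):
    defaults = dict(steps=8000.0, distance_miles=3.5, mvpa_minutes=40.0, calories=520.0)
    defaults.update(metrics)
    return DailyActivityRecord("p1", day, Brand.fitbit, **defaults)


def _questionnaire(pid="p1", completion=date(2019, 3, 1), ibd=IBDType.CD, scdai=120.0):
    return QuestionnaireResponse(
        participant_id=pid,
        completion_date=completion,
        ibd_type=ibd,
        promis={d: 50.0 for d in PROMIS_DOMAINS},
        scdai=scdai,
    )


# ---------------------------------------------------------------------------
# hard-bounds pass

@pytest.mark.parametrize(
    "metrics, blanked",
    [
        ({"mvpa_minutes": 1440.0}, "mvpa_minutes"),  # a full day of activity is invalid
        ({"steps": 200_001.0}, "steps"),
        ({"distance_miles": 150.5}, "distance_miles"),
        ({"calories": 20_001.0}, "calories"),
    ],
)
def test_unrealistic_values_blanked_not_dropped(metrics, blanked):
    records, report = remove_unrealistic([_record(date(2019, 1, 1), **metrics)])
    assert len(records) == 1
    assert getattr(records[0], blanked) is None
    # the other metrics on the same day survive
    others = [f for f in ("steps", "distance_miles", "mvpa_minutes", "calories") if f != blanked]
    assert all(getattr(records[0], f) is not None for f in others)
    assert report.n_unrealistic_removed == 1


def test_boundary_values_kept():
    records, report = remove_unrealistic(
        [_record(date(2019, 1, 1), mvpa_minutes=1439.0, steps=8000.0)]
    )
    assert records[0].mvpa_minutes == 1439.0
    assert report.n_unrealistic_removed == 0


# ---------------------------------------------------------------------------
# Tukey fences

def _quantile_oracle(values, q):
    """Linear-interpolation quantile, written out longhand."""
    values = sorted(values)
    pos = q * (len(values) - 1)
    lo = math.floor(pos)
    frac = pos - lo
    if lo + 1 < len(values):
        return values[lo] * (1 - frac) + values[lo + 1] * frac
    return values[lo]


def test_tukey_blanks_the_planted_outlier():
    days = [date(2019, 1, 1) + timedelta(days=i) for i in range(10)]
    values = list(range(1, 10)) + [1000]
    records = [_record(d, steps=float(v)) for d, v in zip(days, values)]
    cleaned, fences = tukey_outlier_filter(records, "steps")
    q1 = _quantile_oracle(values, 0.25)
    q3 = _quantile_oracle(values, 0.75)
    assert fences == pytest.approx((q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)))
    assert cleaned[-1].steps is None
    assert all(r.steps is not None for r in cleaned[:-1])


def test_tukey_degenerate_spread_removes_nothing():
    records = [_record(date(2019, 1, 1) + timedelta(days=i), steps=7000.0) for i in range(20)]
    cleaned, fences = tukey_outlier_filter(records, "steps")
    assert all(r.steps == 7000.0 for r in cleaned)
    assert fences[0] == fences[1] == 7000.0


def test_tukey_symmetric_sample_trims_both_tails_equally():
    rng = np.random.default_rng(8)
    centre = rng.normal(0.0, 1.0, 400)
    sample = np.concatenate([centre, centre.max() + np.arange(1, 7) * 2, centre.min() - np.arange(1, 7) * 2])
    sample = np.concatenate([sample, -sample])  # exactly symmetric about 0
    days = [date(2019, 1, 1) + timedelta(days=i) for i in range(len(sample))]
    records = [_record(d, distance_miles=None, steps=float(v) + 10_000) for d, v in zip(days, sample)]
    cleaned, (lo, hi) = tukey_outlier_filter(records, "steps")
    removed = [r0.steps - 10_000 for r0, r1 in zip(records, cleaned) if r1.steps is None]
    assert len(removed) > 0
    assert sum(1 for v in removed if v > 0) == sum(1 for v in removed if v < 0)


def test_tukey_needs_four_values():
    records = [_record(date(2019, 1, 1) + timedelta(days=i), steps=float(i)) for i in range(3)]
    cleaned, fences = tukey_outlier_filter(records, "steps")
    assert fences is None and cleaned == records


def test_outlier_removal_rates_on_clean_synthetic_data(full_cohort):
    """Without injected outliers the fences should trim only distribution
    tails. Steps, distance and calories are mildly truncated normals whose
    pooled tails stay light; MVPA minutes has a coefficient of variation
    near 1 in the reference moments, so its zero-truncated distribution is
    intrinsically right-skewed and loses more to the upper fence."""
    _, daily, _, _ = full_cohort
    _, report = clean_daily_records(daily)
    n = len(daily)
    for feature in ("steps", "distance_miles", "calories"):
        assert report.n_outliers_removed[feature] / n < 0.03
    assert report.n_outliers_removed["mvpa_minutes"] / n < 0.06


def test_stable_cleaning_is_exactly_idempotent(small_cohort):
    _, daily, _, _ = small_cohort
    once, _ = clean_daily_records(daily, until_stable=True)
    twice, second_report = clean_daily_records(once, until_stable=True)
    assert twice == once
    assert all(v == 0 for v in second_report.n_outliers_removed.values())


def test_default_cleaning_nearly_idempotent(small_cohort):
    """Single-pass fences recomputed on their own output trim a little
    further (the fences tighten); the drift stays ~1% of cells and a second
    pass removes far less than the first."""
    _, daily, _, _ = small_cohort
    once, first_report = clean_daily_records(daily)
    _, second_report = clean_daily_records(once)
    drift = sum(second_report.n_outliers_removed.values())
    assert drift / (4 * len(daily)) < 0.02
    assert drift < 0.5 * sum(first_report.n_outliers_removed.values())


# ---------------------------------------------------------------------------
# window building

def test_window_eligibility_boundary():
    """21 of 42 days (= ceil(0.5 x 42)) is eligible; 20 is not."""
    completion = date(2019, 3, 1)
    q = _questionnaire(completion=completion)
    for n_days, expected in ((21, 1), (20, 0)):
        records = [
            _record(completion - timedelta(days=i + 1)) for i in range(n_days)
        ]
        windows = build_windows(records, [q])
        assert len(windows) == expected


def test_window_mean_ignores_gaps():
    completion = date(2019, 3, 1)
    days = [completion - timedelta(days=1 + 2 * i) for i in range(21)]  # alternating gaps
    records = [_record(d, steps=7000.0) for d in days]
    (window,) = build_windows(records, [_questionnaire(completion=completion)])
    assert window.mean_steps == pytest.approx(7000.0)
    assert window.days_used == 21


def test_window_excludes_completion_day_and_far_days():
    completion = date(2019, 3, 1)
    inside = [_record(completion - timedelta(days=i)) for i in range(1, 43)]
    outside = [_record(completion), _record(completion - timedelta(days=43))]
    (window,) = build_windows(inside + outside, [_questionnaire(completion=completion)])
    assert window.days_used == 42
    assert window.window_start == completion - timedelta(days=42)
    assert window.window_end == completion - timedelta(days=1)


def test_per_feature_means_use_available_days_only():
    completion = date(2019, 3, 1)
    records = [
        _record(completion - timedelta(days=i + 1), mvpa_minutes=None if i % 2 else 30.0)
        for i in range(30)
    ]
    (window,) = build_windows(records, [_questionnaire(completion=completion)])
    assert window.mean_mvpa_minutes == pytest.approx(30.0)
    assert window.days_used == 30  # day counts as used if any metric present


def test_order_invariance(small_cohort):
    _, daily, questionnaires, _ = small_cohort
    shuffled = list(daily)
    random.Random(3).shuffle(shuffled)
    assert build_windows(daily, questionnaires) == build_windows(shuffled, questionnaires)


def test_emitted_windows_satisfy_coverage(full_cohort):
    _, daily, questionnaires, _ = full_cohort
    windows = build_windows(daily, questionnaires, window_days=42, min_coverage=0.5)
    assert windows
    for w in windows:
        assert w.days_used >= math.ceil(0.5 * 42)
        assert w.days_used <= 42
        assert w.days_used == w.weekday_days_used + w.weekend_days_used


# ---------------------------------------------------------------------------
# wear summary

def _window(days_used, weekday, weekend, start=date(2019, 1, 7)):
    return ActivityWindow(
        participant_id="p",
        questionnaire_date=start + timedelta(days=42),
        window_start=start,
        window_end=start + timedelta(days=41),
        days_used=days_used,
        weekday_days_used=weekday,
        weekend_days_used=weekend,
    )


def test_wear_summary_reproduces_reference_percentages():
    """Windows whose means are 37.3/42 days, 26.9/30 weekdays and 10.4/12
    weekend days give 89.7% weekday and 86.7% weekend wear."""
    windows = (
        [_window(37, 27, 10)] * 6 + [_window(38, 27, 11)] * 3 + [_window(37, 26, 11)]
    )
    summary = wear_summary(windows)
    assert summary.mean_days_used == pytest.approx(37.3)
    assert summary.mean_weekday_days_used == pytest.approx(26.9)
    assert summary.mean_weekend_days_used == pytest.approx(10.4)
    assert round(summary.weekday_percent, 1) == 89.7
    assert round(summary.weekend_percent, 1) == 86.7
    assert summary.weekday_capacity == 30 and summary.weekend_capacity == 12


def test_wear_summary_full_coverage_and_empty_input():
    windows = [_window(42, 30, 12)] * 3
    summary = wear_summary(windows)
    assert summary.percent_of_window == pytest.approx(100.0)
    assert summary.weekday_percent == pytest.approx(100.0)
    assert summary.weekend_percent == pytest.approx(100.0)
    with pytest.raises(ValueError):
        wear_summary([])
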