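"""Cleaning of daily wearable records and aggregation into activity windows.

Cleaning has two passes, both of which blank offending cells rather than
dropping whole rows (other metrics on the same day remain usable):

1. hard physical-plausibility bounds (e.g. an activity duration of a full
   24 hours, or step counts no human reaches);
2. Tukey fences per feature, computed cohort-wide over all daily values:
   values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are blanked.

Cleaned records are then aggregated into one :class:`ActivityWindow` per
questionnaire: per-feature means over the days with data in the
``window_days`` days strictly before questionnaire completion. Windows with
fewer than ``ceil(min_coverage * window_days)`` used days are excluded
(the wear-time eligibility rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ACTIVITY_FEATURES,
    ActivityWindow,
    DailyActivityRecord,
    QuestionnaireResponse,
    daily_to_frame,
    logger,
)

#: Hard plausibility bounds; a cell at/above the bound is blanked.
#: MVPA of 1440 min would be activity for the entire day.
UNREALISTIC_BOUNDS = {
    "mvpa_minutes": 1440.0,  # value >= bound is invalid
    "steps": 200_000.0,  # value > bound is invalid
    "distance_miles": 150.0,
    "calories": 20_000.0,
}


@dataclass
class CleaningReport:
    n_rows_in: int = 0
    n_unrealistic_removed: int = 0
    n_outliers_removed: dict = dc_field(default_factory=dict)
    n_windows_built: int = 0
    n_windows_excluded_coverage: int = 0

    def to_dict(self) -> dict:
        return {
            "n_rows_in": self.n_rows_in,
            "n_unrealistic_removed": self.n_unrealistic_removed,
            "n_outliers_removed": dict(self.n_outliers_removed),
            "n_windows_built": self.n_windows_built,
            "n_windows_excluded_coverage": self.n_windows_excluded_coverage,
        }


def remove_unrealistic(
    records: Sequence[DailyActivityRecord],
    report: CleaningReport | None = None,
) -> tuple[list[DailyActivityRecord], CleaningReport]:
    """Blank metric cells violating hard physical bounds; rows are retained."""
    report = report or CleaningReport(n_rows_in=len(records))
    out: list[DailyActivityRecord] = []
    for r in records:
        r = DailyActivityRecord(**{**r.__dict__})
        if r.mvpa_minutes is not None and r.mvpa_minutes >= UNREALISTIC_BOUNDS["mvpa_minutes"]:
            r.mvpa_minutes = None
            report.n_unrealistic_removed += 1
        for feature in ("steps", "distance_miles", "calories"):
            value = getattr(r, feature)
            if value is not None and value > UNREALISTIC_BOUNDS[feature]:
                setattr(r, feature, None)
                report.n_unrealistic_removed += 1
        out.append(r)
    return out, report


def tukey_fences(values: np.ndarray) -> tuple[float, float]:
    """Lower/upper Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR), quartiles by
    linear interpolation."""
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def tukey_outlier_filter(
    records: Sequence[DailyActivityRecord],
    feature: str,
    report: CleaningReport | None = None,
) -> tuple[list[DailyActivityRecord], tuple[float, float] | None]:
    """Blank cohort-wide Tukey outliers of one feature; returns fences used.

    With fewer than 4 non-absent values the quartiles are too unstable and
    the filter is a warned no-op (fences ``None``).
    """
    values = np.array([getattr(r, feature) for r in records if getattr(r, feature) is not None], dtype=float)
    if values.size < 4:
        logger.warning("tukey filter skipped for %r: only %d values", feature, values.size)
        return list(records), None
    lo, hi = tukey_fences(values)
    out: list[DailyActivityRecord] = []
    n_removed = 0
    for r in records:
        value = getattr(r, feature)
        if value is not None and not (lo <= value <= hi):
            r = DailyActivityRecord(**{**r.__dict__})
            setattr(r, feature, None)
            n_removed += 1
        out.append(r)
    if report is not None:
        report.n_outliers_removed[feature] = report.n_outliers_removed.get(feature, 0) + n_removed
    return out, (lo, hi)


def clean_daily_records(
    records: Sequence[DailyActivityRecord],
    until_stable: bool = False,
) -> tuple[list[DailyActivityRecord], CleaningReport]:
    """Full cleaning pass: hard bounds, then Tukey fences per feature.

    The default applies the fences once, computed from the post-bounds data
    (the conventional reading of Tukey's rule). With ``until_stable`` the
    fences are recomputed and reapplied until no value is removed, which
    makes the whole cleaning exactly idempotent at the cost of trimming
    further into heavy-tailed features.
    """
    report = CleaningReport(n_rows_in=len(records))
    records, report = remove_unrealistic(records, report)
    for feature in ACTIVITY_FEATURES:
        before = report.n_outliers_removed.get(feature, 0)
        records, _ = tukey_outlier_filter(records, feature, report)
        while until_stable and report.n_outliers_removed.get(feature, 0) > before:
            before = report.n_outliers_removed.get(feature, 0)
            records, _ = tukey_outlier_filter(records, feature, report)
    return records, report


def build_windows(
    records: Sequence[DailyActivityRecord],
    questionnaires: Sequence[QuestionnaireResponse],
    window_days: int = 42,
    min_coverage: float = 0.5,
    report: CleaningReport | None = None,
) -> list[ActivityWindow]:
    """Aggregate cleaned daily records into per-questionnaire windows.

    The window is the ``window_days`` days strictly before (not including)
    completion. A day is "used" when at least one activity metric is
    recorded. Per-feature means run over the days with that feature present.
    Windows below the coverage threshold ``ceil(min_coverage * window_days)``
    are dropped (questionnaires without overlapping records simply yield no
    window).
    """
    min_days = math.ceil(min_coverage * window_days)
    frame = daily_to_frame(records) if records else None

    q_frame = pd.DataFrame(
        {
            "participant_id": [q.participant_id for q in questionnaires],
            "q_date": pd.to_datetime([q.completion_date for q in questionnaires]),
        }
    )

    windows: list[ActivityWindow] = []
    n_excluded = 0
    if frame is not None and len(frame):
        frame = frame.dropna(subset=list(ACTIVITY_FEATURES), how="all")
        frame = frame.sort_values("date", kind="stable")
        q_sorted = q_frame.sort_values("q_date", kind="stable")
        merged = pd.merge_asof(
            frame,
            q_sorted.rename(columns={"q_date": "q_match"}),
            left_on="date",
            right_on="q_match",
            by="participant_id",
            direction="forward",
            allow_exact_matches=False,
            tolerance=pd.Timedelta(days=window_days),
        )
        merged = merged.dropna(subset=["q_match"])
        if len(merged):
            merged["is_weekend"] = merged["date"].dt.dayofweek >= 5
            grouped = merged.groupby(["participant_id", "q_match"], sort=True)
            agg = grouped.agg(
                days_used=("date", "size"),
                weekend_days_used=("is_weekend", "sum"),
                mean_steps=("steps", "mean"),
                mean_distance_miles=("distance_miles", "mean"),
                mean_mvpa_minutes=("mvpa_minutes", "mean"),
                mean_calories=("calories", "mean"),
            )
            for (pid, q_match), row in agg.iterrows():
                days_used = int(row["days_used"])
                if days_used < min_days:
                    n_excluded += 1
                    continue
                q_date = q_match.date()
                weekend = int(row["weekend_days_used"])
                windows.append(
                    ActivityWindow(
                        participant_id=pid,
                        questionnaire_date=q_date,
                        window_start=q_date - pd.Timedelta(days=window_days).to_pytimedelta(),
                        window_end=q_date - pd.Timedelta(days=1).to_pytimedelta(),
                        days_used=days_used,
                        weekday_days_used=days_used - weekend,
                        weekend_days_used=weekend,
                        mean_steps=_none_if_nan(row["mean_steps"]),
                        mean_distance_miles=_none_if_nan(row["mean_distance_miles"]),
                        mean_mvpa_minutes=_none_if_nan(row["mean_mvpa_minutes"]),
                        mean_calories=_none_if_nan(row["mean_calories"]),
                    )
                )
    if report is not None:
        report.n_windows_built += len(windows)
        report.n_windows_excluded_coverage += n_excluded
    windows.sort(key=lambda w: (w.participant_id, w.questionnaire_date))
    return windows


def _none_if_nan(value) -> float | None:
    value = float(value)
    return None if math.isnan(value) else value


def weekday_capacity(window: ActivityWindow) -> tuple[int, int]:
    """(weekday, weekend) day counts the window's calendar span contains."""
    days = pd.date_range(window.window_start, window.window_end, freq="D")
    weekend = int((days.dayofweek >= 5).sum())
    return len(days) - weekend, weekend


@dataclass
class WearSummary:
    n_windows: int
    window_days: int
    mean_days_used: float
    sd_days_used: float
    percent_of_window: float
    mean_weekday_days_used: float
    mean_weekend_days_used: float
    weekday_capacity: float
    weekend_capacity: float
    weekday_percent: float
    weekend_percent: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def wear_summary(windows: Sequence[ActivityWindow]) -> WearSummary:
    """Device wear-time summary: mean/SD of days used and percent of the
    window worn, overall and split weekday/weekend (weekend = Sat/Sun)."""
    if not windows:
        raise ValueError("wear_summary requires at least one window")
    days_used = np.array([w.days_used for w in windows], dtype=float)
    weekday_used = np.array([w.weekday_days_used for w in windows], dtype=float)
    weekend_used = np.array([w.weekend_days_used for w in windows], dtype=float)
    capacities = np.array([weekday_capacity(w) for w in windows], dtype=float)
    window_days = int(np.round(capacities.sum(axis=1).mean()))
    wk_cap = float(capacities[:, 0].mean())
    we_cap = float(capacities[:, 1].mean())
    return WearSummary(
        n_windows=len(windows),
        window_days=window_days,
        mean_days_used=float(days_used.mean()),
        sd_days_used=float(days_used.std(ddof=1)) if len(windows) > 1 else 0.0,
        percent_of_window=100.0 * days_used.mean() / window_days,
        mean_weekday_days_used=float(weekday_used.mean()),
        mean_weekend_days_used=float(weekend_used.mean()),
        weekday_capacity=wk_cap,
        weekend_capacity=we_cap,
        weekday_percent=100.0 * weekday_used.mean() / wk_cap,
        weekend_percent=100.0 * weekend_used.mean() / we_cap,
    )
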