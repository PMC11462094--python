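"""Shared data model, disease-activity scoring bands, and CSV readers/writers.

The pipeline works with three kinds of records:

* :class:`DailyActivityRecord` — one device-day of raw activity metrics
  (steps, distance in miles, moderate-to-vigorous minutes, activity calories).
* :class:`QuestionnaireResponse` — one biannual questionnaire: six PROMIS
  T-scores, the disease-activity index matching the IBD subtype (SCDAI for
  Crohn disease, SCCAI for ulcerative/indeterminate colitis), and
  sociodemographic/clinical covariates.
* :class:`ActivityWindow` — the per-questionnaire aggregation of daily
  records over the weeks preceding questionnaire completion.

All interchange is plain CSV (comma-separated, UTF-8, header required,
ISO-8601 dates). Empty cells denote absent values; negative metrics are
rejected at parse time.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields
from datetime import date as Date
from datetime import datetime
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("actiphen")

#: PROMIS health-related quality-of-life domains scored as T-scores
#: (population mean 50, SD 10). Higher = more of the measured concept.
PROMIS_DOMAINS = (
    "anxiety",
    "depression",
    "pain_interference",
    "fatigue",
    "sleep_disturbance",
    "social_satisfaction",
)

#: Daily activity metrics carried by every record, in standardized units
#: (count, miles, minutes, kcal).
ACTIVITY_FEATURES = ("steps", "distance_miles", "mvpa_minutes", "calories")

SCCAI_MAX = 19.0


def percent(n: float, total: float, digits: int = 1) -> float:
    """Share of ``total`` as a percentage, rounded for reporting."""
    if total == 0:
        raise ValueError("percentage of an empty total is undefined")
    return round(100.0 * n / total, digits)


class ParseError(ValueError):
    """Raised when a CSV row cannot be converted into a valid record."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a documented invariant."""


class Brand(str, Enum):
    fitbit = "fitbit"
    garmin = "garmin"
    jawbone = "jawbone"
    under_armour = "under_armour"
    other = "other"


class IBDType(str, Enum):
    CD = "CD"
    UC_IC = "UC_IC"


class DiseaseIndex(str, Enum):
    SCDAI = "SCDAI"
    SCCAI = "SCCAI"


@dataclass
class DailyActivityRecord:
    """One device-day of activity. Any metric may be absent (None), never negative."""

    participant_id: str
    date: Date
    brand: Brand = Brand.other
    steps: float | None = None
    distance_miles: float | None = None
    mvpa_minutes: float | None = None
    calories: float | None = None


@dataclass
class QuestionnaireResponse:
    """One PRO questionnaire: PROMIS T-scores plus the subtype-matched disease index."""

    participant_id: str
    completion_date: Date
    ibd_type: IBDType
    promis: dict[str, float | None] = field(default_factory=dict)
    scdai: float | None = None
    sccai: float | None = None
    covariates: dict[str, object] = field(default_factory=dict)

    @property
    def disease_score(self) -> float | None:
        """The disease-activity score for the subtype's own index."""
        return self.scdai if self.ibd_type is IBDType.CD else self.sccai


@dataclass
class ActivityWindow:
    """Aggregated activity over the ``window_days`` strictly before a questionnaire."""

    participant_id: str
    questionnaire_date: Date
    window_start: Date
    window_end: Date  # inclusive; the day before questionnaire completion
    days_used: int = 0
    weekday_days_used: int = 0
    weekend_days_used: int = 0
    mean_steps: float | None = None
    mean_distance_miles: float | None = None
    mean_mvpa_minutes: float | None = None
    mean_calories: float | None = None

    @property
    def window_days(self) -> int:
        return (self.window_end - self.window_start).days + 1


@dataclass(frozen=True)
class DiseaseActivityBand:
    index: DiseaseIndex
    score: float
    band: str  # remission | mild | moderate | severe | active

    @property
    def active(self) -> bool:
        return self.band != "remission"


def classify_disease_activity(index: DiseaseIndex | str, score: float) -> DiseaseActivityBand:
    """Map a disease-activity score to its clinical band.

    SCDAI: <150 remission; 150-219 mild; 220-450 moderate; >450 severe.
    SCCAI: <2.5 remission; >=2.5 active.
    """
    index = DiseaseIndex(index)
    if not math.isfinite(score) or score < 0:
        raise ValidationError(f"disease score must be finite and >= 0, got {score!r}")
    if index is DiseaseIndex.SCDAI:
        if score < 150:
            band = "remission"
        elif score < 220:
            band = "mild"
        elif score <= 450:
            band = "moderate"
        else:
            band = "severe"
    else:
        band = "remission" if score < 2.5 else "active"
    return DiseaseActivityBand(index=index, score=score, band=band)


# ---------------------------------------------------------------------------
# CSV parsing helpers

DAILY_HEADER = [
    "participant_id",
    "date",
    "brand",
    "steps",
    "distance_miles",
    "mvpa_minutes",
    "calories",
]

QUESTIONNAIRE_BASE_HEADER = (
    ["participant_id", "completion_date", "ibd_type"]
    + [f"promis_{d}" for d in PROMIS_DOMAINS]
    + ["scdai", "sccai"]
)


def _parse_date(raw: str, row: int, column: str) -> Date:
    try:
        return datetime.strptime(raw, "%Y-%m-%d").date()
    except ValueError as exc:
        raise ParseError(f"row {row}: malformed ISO date in {column!r}: {raw!r}") from exc


def _parse_metric(raw: str, row: int, column: str) -> float | None:
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise ParseError(f"row {row}: non-numeric value in {column!r}: {raw!r}") from exc
    if not math.isfinite(value) or value < 0:
        raise ParseError(f"row {row}: negative or non-finite {column!r}: {raw!r}")
    return value


def read_daily_records(path) -> list[DailyActivityRecord]:
    """Read daily activity records from CSV, preserving row order.

    The header must be exactly ``participant_id,date,brand,steps,
    distance_miles,mvpa_minutes,calories``. Empty cells become absent
    metrics; malformed dates and negative metrics raise :class:`ParseError`
    naming the offending row (1-based, counting the header as row 1).
    """
    records: list[DailyActivityRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != DAILY_HEADER:
            raise ParseError(f"unexpected daily-record header: {header!r}")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(DAILY_HEADER):
                raise ParseError(f"row {row_no}: expected {len(DAILY_HEADER)} fields, got {len(row)}")
            pid, rawdate, rawbrand = row[0], row[1], row[2]
            try:
                brand = Brand(rawbrand) if rawbrand else Brand.other
            except ValueError as exc:
                raise ParseError(f"row {row_no}: unknown device brand {rawbrand!r}") from exc
            records.append(
                DailyActivityRecord(
                    participant_id=pid,
                    date=_parse_date(rawdate, row_no, "date"),
                    brand=brand,
                    steps=_parse_metric(row[3], row_no, "steps"),
                    distance_miles=_parse_metric(row[4], row_no, "distance_miles"),
                    mvpa_minutes=_parse_metric(row[5], row_no, "mvpa_minutes"),
                    calories=_parse_metric(row[6], row_no, "calories"),
                )
            )
    return records


def write_daily_records(records: Iterable[DailyActivityRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(DAILY_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.date.isoformat(),
                    r.brand.value,
                    _fmt(r.steps),
                    _fmt(r.distance_miles),
                    _fmt(r.mvpa_minutes),
                    _fmt(r.calories),
                ]
            )


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def read_questionnaires(path) -> list[QuestionnaireResponse]:
    """Read questionnaire responses from CSV.

    Required columns: participant_id, completion_date, ibd_type,
    promis_<domain> for the six PROMIS domains, scdai, sccai. Any further
    columns are kept verbatim as covariates. Records are returned sorted by
    (participant_id, completion_date); duplicate (id, date) pairs and
    out-of-range scores raise :class:`ValidationError`.
    """
    responses: list[QuestionnaireResponse] = []
    seen: set[tuple[str, Date]] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ParseError("empty questionnaire file")
        missing = [c for c in QUESTIONNAIRE_BASE_HEADER if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"questionnaire file missing columns: {missing}")
        covariate_cols = [c for c in reader.fieldnames if c not in QUESTIONNAIRE_BASE_HEADER]
        for row_no, row in enumerate(reader, start=2):
            pid = row["participant_id"]
            cdate = _parse_date(row["completion_date"], row_no, "completion_date")
            key = (pid, cdate)
            if key in seen:
                raise ValidationError(f"row {row_no}: duplicate questionnaire for {pid} on {cdate}")
            seen.add(key)
            try:
                ibd_type = IBDType(row["ibd_type"])
            except ValueError as exc:
                raise ParseError(f"row {row_no}: unknown ibd_type {row['ibd_type']!r}") from exc
            promis = {d: _parse_metric(row[f"promis_{d}"], row_no, f"promis_{d}") for d in PROMIS_DOMAINS}
            scdai = _parse_metric(row["scdai"], row_no, "scdai")
            sccai = _parse_metric(row["sccai"], row_no, "sccai")
            if sccai is not None and sccai > SCCAI_MAX:
                raise ValidationError(f"row {row_no}: SCCAI {sccai} outside [0, {SCCAI_MAX}]")
            if scdai is not None and scdai > 600:
                logger.warning("row %d: SCDAI %.1f above the usual 600 ceiling; accepted", row_no, scdai)
            if ibd_type is IBDType.CD and sccai is not None:
                raise ValidationError(f"row {row_no}: SCCAI reported for a Crohn disease participant")
            if ibd_type is IBDType.UC_IC and scdai is not None:
                raise ValidationError(f"row {row_no}: SCDAI reported for a UC/IC participant")
            covariates = {c: row[c] for c in covariate_cols}
            responses.append(
                QuestionnaireResponse(
                    participant_id=pid,
                    completion_date=cdate,
                    ibd_type=ibd_type,
                    promis=promis,
                    scdai=scdai,
                    sccai=sccai,
                    covariates=covariates,
                )
            )
    responses.sort(key=lambda q: (q.participant_id, q.completion_date))
    return responses


def write_questionnaires(responses: Sequence[QuestionnaireResponse], path) -> None:
    covariate_cols: list[str] = []
    for q in responses:
        for c in q.covariates:
            if c not in covariate_cols:
                covariate_cols.append(c)
    header = QUESTIONNAIRE_BASE_HEADER + covariate_cols
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(header)
        for q in responses:
            row = [q.participant_id, q.completion_date.isoformat(), q.ibd_type.value]
            row += [_fmt(q.promis.get(d)) for d in PROMIS_DOMAINS]
            row += [_fmt(q.scdai), _fmt(q.sccai)]
            row += ["" if q.covariates.get(c) is None else str(q.covariates.get(c)) for c in covariate_cols]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# DataFrame views (internal bulk-processing surface)

def daily_to_frame(records: Sequence[DailyActivityRecord]) -> pd.DataFrame:
    """Columnar view of daily records used by the preprocessing stages."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "date": pd.to_datetime([r.date for r in records]),
            "brand": [r.brand.value for r in records],
            "steps": [r.steps for r in records],
            "distance_miles": [r.distance_miles for r in records],
            "mvpa_minutes": [r.mvpa_minutes for r in records],
            "calories": [r.calories for r in records],
        }
    )


def windows_to_frame(windows: Sequence[ActivityWindow]) -> pd.DataFrame:
    cols = [f.name for f in fields(ActivityWindow)]
    data = {c: [getattr(w, c) for w in windows] for c in cols}
    return pd.DataFrame(data)


def write_windows(windows: Sequence[ActivityWindow], path) -> None:
    frame = windows_to_frame(windows)
    for col in ("questionnaire_date", "window_start", "window_end"):
        frame[col] = [d.isoformat() for d in frame[col]]
    frame.to_csv(path, index=False)


def read_windows(path) -> list[ActivityWindow]:
    frame = pd.read_csv(path, keep_default_na=True)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            ActivityWindow(
                participant_id=str(row.participant_id),
                questionnaire_date=_iso(row.questionnaire_date),
                window_start=_iso(row.window_start),
                window_end=_iso(row.window_end),
                days_used=int(row.days_used),
                weekday_days_used=int(row.weekday_days_used),
                weekend_days_used=int(row.weekend_days_used),
                mean_steps=_nan_none(row.mean_steps),
                mean_distance_miles=_nan_none(row.mean_distance_miles),
                mean_mvpa_minutes=_nan_none(row.mean_mvpa_minutes),
                mean_calories=_nan_none(row.mean_calories),
            )
        )
    return out


def _iso(raw: str) -> Date:
    return datetime.strptime(str(raw), "%Y-%m-%d").date()


def _nan_none(value) -> float | None:
    value = float(value)
    return None if math.isnan(value) else value
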