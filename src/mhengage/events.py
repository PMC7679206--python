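"""Event-log and user-profile data model, readers/writers, and validation.

The unit of observation is one app entry: a user interacting with one of
five modules (medication, food, exercise, blood glucose, continuous glucose
monitoring).  Each record carries the time the behaviour occurred
(``event_time``, per user indication or device) and the time the record
entered the app (``entry_time``).  Engagement metrics are computed on
*active days* — calendar days with at least one entry — so the reader
validates and normalises timestamps up front and rejects malformed rows
with an explicit report rather than coercing them silently.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Module",
    "MealTag",
    "MedType",
    "EventRecord",
    "MedicationEntry",
    "UserProfile",
    "ValidationReport",
    "DateWindow",
    "read_events",
    "write_events",
    "read_profiles",
    "write_profiles",
    "events_to_frame",
    "frame_to_events",
    "filter_preconsent",
    "apply_plausibility",
    "active_days",
]

# Self-report plausibility bounds; values outside become unknown, rows are kept.
AGE_BOUNDS = (16, 100)
HEIGHT_BOUNDS = (140.0, 220.0)
WEIGHT_BOUNDS = (45.0, 300.0)


class Module(str, Enum):
    MEDICATION = "medication"
    FOOD = "food"
    EXERCISE = "exercise"
    BG = "bg"
    CGM = "cgm"


MODULES: tuple[Module, ...] = tuple(Module)


class MealTag(str, Enum):
    FASTING = "fasting"
    PREPRANDIAL = "preprandial"
    POSTPRANDIAL = "postprandial"
    NONE = "none"


class MedType(str, Enum):
    ORAL = "oral"
    INSULIN = "insulin"
    OTHER_INJECTABLE = "other_injectable"


@dataclass(frozen=True)
class EventRecord:
    """One app entry.

    ``entry_time`` is mandatory (the interaction with the app);
    ``event_time`` is the user- or device-indicated behaviour time and may
    be absent, in which case consumers fall back to ``entry_time``.
    ``value`` is a glucose reading in mg/dL, present iff the module is
    bg or cgm.
    """

    user_id: str
    module: Module
    entry_time: datetime
    event_time: datetime | None = None
    value: float | None = None
    meal_tag: MealTag | None = None

    @property
    def effective_time(self) -> datetime:
        return self.event_time if self.event_time is not None else self.entry_time


@dataclass(frozen=True)
class MedicationEntry:
    name: str
    med_type: MedType
    start_date: date
    is_bolus: bool = False

    def __post_init__(self) -> None:
        if self.is_bolus and self.med_type is not MedType.INSULIN:
            raise ValueError("is_bolus requires med_type=insulin")


@dataclass
class UserProfile:
    user_id: str
    consent_date: date
    gender: str | None = None            # "female" | "male"
    age: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    diabetes_type: str | None = None     # "t1d" | "t2d" | "prediabetes" | "other"
    medications: list[MedicationEntry] = field(default_factory=list)


@dataclass
class ValidationReport:
    """Counts of rejected rows by reason, plus per-field missingness."""

    n_read: int = 0
    n_accepted: int = 0
    rejected: Counter = field(default_factory=Counter)
    missingness: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rejected[reason] += 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


@dataclass(frozen=True)
class DateWindow:
    """Observation window: ``length_days`` days starting at ``anchor``.

    Day indices are 1-based: day 1 is the anchor date itself.
    """

    anchor: date
    length_days: int = 180

    def __post_init__(self) -> None:
        if self.length_days < 1:
            raise ValueError("length_days must be >= 1")

    @property
    def end(self) -> date:
        """Last calendar date inside the window."""
        return self.anchor + timedelta(days=self.length_days - 1)

    def day_index(self, d: date) -> int:
        """1-based day index of ``d``; may fall outside [1, length_days]."""
        return (d - self.anchor).days + 1


# ---------------------------------------------------------------------------
# parsing helpers

_VALID_MODULES = {m.value for m in Module}
_VALID_TAGS = {t.value for t in MealTag}
_GENDERS = {"female", "male"}
_DIABETES_TYPES = {"t1d", "t2d", "prediabetes", "other"}


def _parse_ts(raw: str | None) -> datetime | None:
    if raw is None or raw == "":
        return None
    ts = datetime.fromisoformat(str(raw))
    if ts.tzinfo is not None:  # single-timezone convention (UTC): convert, then drop tz
        ts = ts.astimezone(timezone.utc).replace(tzinfo=None)
    return ts


def _parse_event_row(row: dict, report: ValidationReport) -> EventRecord | None:
    report.n_read += 1
    module_raw = (row.get("module") or "").strip()
    if module_raw not in _VALID_MODULES:
        report.reject("unknown_module")
        return None
    user_id = (row.get("user_id") or "").strip()
    if not user_id:
        report.reject("missing_user_id")
        return None
    try:
        entry_time = _parse_ts(row.get("entry_time"))
    except ValueError:
        report.reject("bad_entry_time")
        return None
    if entry_time is None:
        report.reject("missing_entry_time")
        return None
    try:
        event_time = _parse_ts(row.get("event_time"))
    except ValueError:
        report.reject("bad_event_time")
        return None

    value_raw = row.get("value")
    value: float | None = None
    if value_raw not in (None, ""):
        try:
            value = float(value_raw)
        except (TypeError, ValueError):
            report.reject("bad_value")
            return None
    module = Module(module_raw)
    if module in (Module.BG, Module.CGM):
        if value is None or value <= 0:
            report.reject("missing_or_nonpositive_glucose")
            return None
    tag_raw = row.get("meal_tag")
    meal_tag: MealTag | None = None
    if tag_raw not in (None, ""):
        if str(tag_raw) not in _VALID_TAGS:
            report.reject("unknown_meal_tag")
            return None
        meal_tag = MealTag(str(tag_raw))
    report.n_accepted += 1
    return EventRecord(user_id=user_id, module=module, entry_time=entry_time,
                       event_time=event_time, value=value, meal_tag=meal_tag)


def _iter_rows(path: Path, fmt: str) -> Iterable[dict]:
    if fmt == "csv":
        with open(path, newline="") as fh:
            yield from csv.DictReader(fh)
    elif fmt == "jsonl":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield json.loads(line)
    else:
        raise ValueError(f"unsupported format: {fmt!r}")


def read_events(path: str | Path, fmt: str = "csv") -> tuple[list[EventRecord], ValidationReport]:
    """Read and validate an event log.

    Malformed rows are rejected with a per-reason count in the returned
    report; valid records come back sorted by (user_id, module, entry_time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ValidationReport()
    records = []
    for row in _iter_rows(path, fmt):
        rec = _parse_event_row(row, report)
        if rec is not None:
            records.append(rec)
    records.sort(key=lambda r: (r.user_id, r.module.value, r.entry_time))
    return records, report


_EVENT_COLUMNS = ["user_id", "module", "event_time", "entry_time", "value", "meal_tag"]


def write_events(records: Sequence[EventRecord], path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    rows = (
        {
            "user_id": r.user_id,
            "module": r.module.value,
            "event_time": r.event_time.isoformat() if r.event_time else "",
            "entry_time": r.entry_time.isoformat(),
            "value": "" if r.value is None else repr(r.value),
            "meal_tag": r.meal_tag.value if r.meal_tag else "",
        }
        for r in records
    )
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_EVENT_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps({k: v for k, v in row.items() if v != ""}) + "\n")
    else:
        raise ValueError(f"unsupported format: {fmt!r}")


def events_to_frame(records: Sequence[EventRecord]) -> pd.DataFrame:
    """Columnar view of an event log for bulk metric computation."""
    return pd.DataFrame(
        {
            "user_id": [r.user_id for r in records],
            "module": [r.module.value for r in records],
            "entry_time": pd.to_datetime([r.entry_time for r in records]),
            "event_time": pd.to_datetime([r.effective_time for r in records]),
            "value": [r.value for r in records],
            "meal_tag": [r.meal_tag.value if r.meal_tag else None for r in records],
        }
    )


def frame_to_events(df: pd.DataFrame) -> list[EventRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EventRecord(
                user_id=str(row.user_id),
                module=Module(row.module),
                entry_time=row.entry_time.to_pydatetime(),
                event_time=(None if pd.isna(getattr(row, "event_time", None))
                            else row.event_time.to_pydatetime()),
                value=None if pd.isna(getattr(row, "value", None)) else float(row.value),
                meal_tag=(MealTag(row.meal_tag)
                          if getattr(row, "meal_tag", None) not in (None, "")
                          and not pd.isna(row.meal_tag) else None),
            )
        )
    return out


# ---------------------------------------------------------------------------
# profiles


def apply_plausibility(profile: UserProfile) -> UserProfile:
    """Replace implausible self-reported values by absent (rows are kept).

    Idempotent: bounds are closed, so an already-filtered profile passes
    through unchanged.
    """
    p = profile
    if p.age is not None and not (AGE_BOUNDS[0] <= p.age <= AGE_BOUNDS[1]):
        p.age = None
    if p.height_cm is not None and not (HEIGHT_BOUNDS[0] <= p.height_cm <= HEIGHT_BOUNDS[1]):
        p.height_cm = None
    if p.weight_kg is not None and not (WEIGHT_BOUNDS[0] <= p.weight_kg <= WEIGHT_BOUNDS[1]):
        p.weight_kg = None
    return p


def _opt_float(raw) -> float | None:
    if raw in (None, ""):
        return None
    return float(raw)


def read_profiles(
    path: str | Path, medications_path: str | Path | None = None
) -> tuple[list[UserProfile], ValidationReport]:
    """Read user profiles (one row per user) plus an optional medication registry.

    Implausible age/height/weight values are set absent with a count in the
    report's missingness tally; a duplicate user_id is fatal.
    """
    path = Path(path)
    report = ValidationReport()
    meds_by_user: dict[str, list[MedicationEntry]] = {}
    if medications_path is not None:
        with open(medications_path, newline="") as fh:
            for row in csv.DictReader(fh):
                entry = MedicationEntry(
                    name=row["name"],
                    med_type=MedType(row["med_type"]),
                    start_date=date.fromisoformat(row["start_date"]),
                    is_bolus=str(row.get("is_bolus", "")).lower() in ("1", "true", "yes"),
                )
                meds_by_user.setdefault(row["user_id"], []).append(entry)

    profiles: list[UserProfile] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            report.n_read += 1
            uid = row["user_id"]
            if uid in seen:
                raise ValueError(f"duplicate user_id in profiles: {uid!r}")
            seen.add(uid)
            gender = row.get("gender") or None
            if gender is not None and gender not in _GENDERS:
                gender = None
            dtype = row.get("diabetes_type") or None
            if dtype is not None and dtype not in _DIABETES_TYPES:
                dtype = None
            prof = UserProfile(
                user_id=uid,
                consent_date=date.fromisoformat(row["consent_date"]),
                gender=gender,
                age=_opt_float(row.get("age")),
                height_cm=_opt_float(row.get("height_cm")),
                weight_kg=_opt_float(row.get("weight_kg")),
                diabetes_type=dtype,
                medications=meds_by_user.get(uid, []),
            )
            apply_plausibility(prof)
            for field_name in ("gender", "age", "height_cm", "weight_kg", "diabetes_type"):
                if getattr(prof, field_name) is None:
                    report.missingness[field_name] += 1
            if not prof.medications:
                report.missingness["medications"] += 1
            report.n_accepted += 1
            profiles.append(prof)
    return profiles, report


def write_profiles(
    profiles: Sequence[UserProfile],
    path: str | Path,
    medications_path: str | Path | None = None,
) -> None:
    cols = ["user_id", "consent_date", "gender", "age", "height_cm", "weight_kg", "diabetes_type"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for p in profiles:
            writer.writerow(
                {
                    "user_id": p.user_id,
                    "consent_date": p.consent_date.isoformat(),
                    "gender": p.gender or "",
                    "age": "" if p.age is None else p.age,
                    "height_cm": "" if p.height_cm is None else p.height_cm,
                    "weight_kg": "" if p.weight_kg is None else p.weight_kg,
                    "diabetes_type": p.diabetes_type or "",
                }
            )
    if medications_path is not None:
        with open(medications_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["user_id", "name", "med_type", "start_date", "is_bolus"]
            )
            writer.writeheader()
            for p in profiles:
                for m in p.medications:
                    writer.writerow(
                        {
                            "user_id": p.user_id,
                            "name": m.name,
                            "med_type": m.med_type.value,
                            "start_date": m.start_date.isoformat(),
                            "is_bolus": int(m.is_bolus),
                        }
                    )


def filter_preconsent(
    df: pd.DataFrame, profiles: Sequence[UserProfile]
) -> tuple[pd.DataFrame, int]:
    """Drop events whose entry_time precedes the user's consent date.

    Consent gates data use; the number of dropped rows is returned so
    pipelines can log it. Users without a profile keep all their events.
    """
    consent = {p.user_id: pd.Timestamp(p.consent_date) for p in profiles}
    cd = df["user_id"].map(consent)
    keep = cd.isna() | (df["entry_time"].dt.normalize() >= cd)
    return df.loc[keep].reset_index(drop=True), int((~keep).sum())


def active_days(
    events: pd.DataFrame | Sequence[EventRecord],
    user: str,
    module: str | Module | None,
    window: DateWindow,
    timestamp: str = "entry",
) -> list[int]:
    """Distinct 1-based day indices with at least one entry, within the window.

    ``timestamp`` selects which clock defines an active day: ``"entry"``
    (when the record entered the app — the interaction being measured,
    default) or ``"event"`` (when the behaviour occurred). ``module=None``
    pools all modules. Day boundaries are calendar dates in a single
    timezone.
    """
    if not isinstance(events, pd.DataFrame):
        events = events_to_frame(list(events))
    col = "entry_time" if timestamp == "entry" else "event_time"
    sub = events[events["user_id"] == user]
    if module is not None:
        mod = module.value if isinstance(module, Module) else module
        sub = sub[sub["module"] == mod]
    if sub.empty:
        return []
    days = (sub[col].dt.normalize() - pd.Timestamp(window.anchor)).dt.days + 1
    idx = sorted(set(int(d) for d in days if 1 <= d <= window.length_days))
    return idx
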