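"""Regression covariates derived from profiles and measurement streams.

Self-reported mHealth data is heavily incomplete, so every categorical
covariate carries an explicit ``unknown`` level rather than dropping rows:
missingness itself is informative about engagement.  The derivation rules
are:

* BMI classes per the WHO cut points (underweight < 18.5 <= normal < 25 <=
  overweight < 30 <= obese I < 35 <= obese II < 40 <= obese III), with the
  three obesity classes collapsed to one "obese" level for regression;
* a recently-diagnosed proxy from the medication registry (insulin started
  within 180 days before consent for type 1; metformin-only regimens
  started within 180 days for type 2);
* baseline fasting blood-glucose control: first preprandial/fasting-tagged
  reading, else first early-morning (05:00-09:00) reading, inside the ADA
  80-130 mg/dL band;
* CGM time-in-range control: >= 70% of readings in 70-180 mg/dL over the
  first 14 days of CGM observation, requiring >= 70% sensor coverage at a
  5-minute cadence.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortMember
from .events import MedType, Module, UserProfile

__all__ = [
    "FeatureVector", "MedicationFlags",
    "bmi_class", "age_group", "recently_diagnosed",
    "fasting_bg_control", "tir_control",
    "build_features", "descriptives",
    "AGE_LEVELS", "BMI_LEVELS", "BMI_LEVELS_FINE",
]

UNKNOWN = "unknown"

AGE_LEVELS = ("<30", "30-40", "40-50", "50-60", "60-70", ">70", UNKNOWN)
BMI_LEVELS_FINE = ("underweight", "normal", "overweight",
                   "obese_1", "obese_2", "obese_3", UNKNOWN)
BMI_LEVELS = ("underweight", "normal", "overweight", "obese", UNKNOWN)

METFORMIN_SYNONYMS = ("metformin", "glucophage", "glumetza", "fortamet", "riomet")

RECENT_LOOKBACK_DAYS = 180
FASTING_BAND = (80.0, 130.0)        # mg/dL, ADA fasting target
NIGHTTIME_WINDOW = (5, 9)           # hours of day, inclusive start/end
TIR_BAND = (70.0, 180.0)            # mg/dL
TIR_TARGET = 0.70
CGM_EXPECTED_PER_DAY = 288          # 5-minute cadence
CGM_COVERAGE_MIN = 0.70
TIR_SPAN_DAYS = 14


@dataclass
class MedicationFlags:
    any_insulin: bool = False
    any_bolus: bool = False
    any_other_injectable: bool = False
    any_oral: bool = False
    n_medications: int = 0
    n_oral_substances: int = 0


@dataclass
class FeatureVector:
    """Covariate vector with unknown as a first-class level (never null)."""

    user_id: str
    gender: str = UNKNOWN
    age_group: str = UNKNOWN
    bmi_group: str = UNKNOWN
    bmi_group_fine: str = UNKNOWN
    diagnosis: str = UNKNOWN
    recent: str = UNKNOWN
    insulin: str = UNKNOWN
    bg_control: str = UNKNOWN
    n_modules_used: int = 1


def bmi_class(height_cm: float | None, weight_kg: float | None,
              collapse_obese: bool = True) -> str:
    """WHO BMI class from self-reported height and weight.

    ``collapse_obese=True`` merges obese I-III into one regression level;
    the fine classes serve the descriptive table.  Any absent input yields
    unknown.
    """
    if height_cm is None or weight_kg is None:
        return UNKNOWN
    bmi = weight_kg / (height_cm / 100.0) ** 2
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    if collapse_obese:
        return "obese"
    if bmi < 35:
        return "obese_1"
    if bmi < 40:
        return "obese_2"
    return "obese_3"


def age_group(age: float | None) -> str:
    """Decade bins with lower-closed boundaries (50 falls in 50-60)."""
    if age is None:
        return UNKNOWN
    if age < 30:
        return "<30"
    if age < 40:
        return "30-40"
    if age < 50:
        return "40-50"
    if age < 60:
        return "50-60"
    if age < 70:
        return "60-70"
    return ">70"


def medication_flags(profile: UserProfile) -> MedicationFlags:
    meds = profile.medications
    return MedicationFlags(
        any_insulin=any(m.med_type is MedType.INSULIN for m in meds),
        any_bolus=any(m.is_bolus for m in meds),
        any_other_injectable=any(m.med_type is MedType.OTHER_INJECTABLE for m in meds),
        any_oral=any(m.med_type is MedType.ORAL for m in meds),
        n_medications=len(meds),
        n_oral_substances=sum(m.med_type is MedType.ORAL for m in meds),
    )


def _is_metformin(name: str) -> bool:
    low = name.lower()
    return any(s in low for s in METFORMIN_SYNONYMS)


def recently_diagnosed(profile: UserProfile,
                       lookback_days: int = RECENT_LOOKBACK_DAYS) -> str:
    """Proxy for a recent first diabetes diagnosis from the medication registry.

    Type 1: insulin treatment started within ``lookback_days`` before
    consent.  Type 2: the regimen is metformin only and started within the
    lookback.  A known diabetes type failing the rule gives "no"; a missing
    type or missing medication profile gives "unknown".
    """
    if profile.diabetes_type is None or not profile.medications:
        return UNKNOWN
    consent = profile.consent_date
    lo = consent - timedelta(days=lookback_days)
    if profile.diabetes_type == "t1d":
        starts = [m.start_date for m in profile.medications
                  if m.med_type is MedType.INSULIN]
        if not starts:
            return "no"
        first = min(starts)
        return "yes" if lo <= first <= consent else "no"
    if profile.diabetes_type == "t2d":
        if not all(_is_metformin(m.name) for m in profile.medications):
            return "no"
        first = min(m.start_date for m in profile.medications)
        return "yes" if lo <= first <= consent else "no"
    return "no"  # prediabetes / other: the rule defines no recent proxy


def fasting_bg_control(bg_events: pd.DataFrame) -> str:
    """Baseline fasting glucose control (yes/no/unknown) for one user.

    The baseline reading is the earliest record tagged fasting or
    preprandial; failing that, the earliest record whose behaviour time of
    day falls in the 05:00-09:00 nighttime-fast window.  Control means the
    value lies in 80-130 mg/dL.
    """
    sub = bg_events[bg_events["module"] == Module.BG.value]
    if sub.empty:
        return UNKNOWN
    sub = sub.sort_values("event_time")
    tagged = sub[sub["meal_tag"].isin(["fasting", "preprandial"])]
    if not tagged.empty:
        baseline = tagged.iloc[0]
    else:
        hours = sub["event_time"].dt.hour
        morning = sub[(hours >= NIGHTTIME_WINDOW[0]) & (hours < NIGHTTIME_WINDOW[1])]
        if morning.empty:
            return UNKNOWN
        baseline = morning.iloc[0]
    value = float(baseline["value"])
    return "yes" if FASTING_BAND[0] <= value <= FASTING_BAND[1] else "no"


def tir_control(cgm_events: pd.DataFrame) -> str:
    """CGM time-in-range control over the user's first 14 days of CGM data.

    Duplicate timestamps are deduplicated; sufficiency requires coverage of
    at least 70% of the expected 5-minute samples across the 14-day span.
    TIR >= 70% (readings within 70-180 mg/dL) means good control.
    """
    sub = cgm_events[cgm_events["module"] == Module.CGM.value]
    if sub.empty:
        return UNKNOWN
    sub = sub.drop_duplicates(subset=["event_time"]).sort_values("event_time")
    first_day = sub["event_time"].dt.normalize().min()
    span_end = first_day + pd.Timedelta(days=TIR_SPAN_DAYS)
    in_span = sub[(sub["event_time"] >= first_day) & (sub["event_time"] < span_end)]
    expected = TIR_SPAN_DAYS * CGM_EXPECTED_PER_DAY
    if len(in_span) < CGM_COVERAGE_MIN * expected:
        return UNKNOWN
    values = in_span["value"].astype(float)
    tir = ((values >= TIR_BAND[0]) & (values <= TIR_BAND[1])).mean()
    return "yes" if tir >= TIR_TARGET else "no"


def build_features(
    profiles: Sequence[UserProfile],
    events: pd.DataFrame,
    metrics: pd.DataFrame,
    cohort: Sequence[CohortMember],
) -> pd.DataFrame:
    """One feature row per cohort member (FeatureVector + MedicationFlags).

    The insulin level is "insulin" if any registered medication is insulin,
    "noninsulin" if a medication profile exists without insulin, and
    "unknown" without a profile.  ``n_modules_used`` counts modules with at
    least one active day inside the window.
    """
    prof_by_id = {p.user_id: p for p in profiles}
    module_counts = (
        metrics[metrics["module"] != "any"].groupby("user_id")["module"].nunique()
        if not metrics.empty else pd.Series(dtype=int)
    )
    by_user = {uid: sub for uid, sub in
               events[events["module"].isin([Module.BG.value, Module.CGM.value])]
               .groupby("user_id")}
    empty = events.iloc[0:0]
    rows = []
    for member in cohort:
        p = prof_by_id[member.user_id]
        flags = medication_flags(p)
        sub = by_user.get(member.user_id, empty)
        fv = FeatureVector(
            user_id=member.user_id,
            gender=p.gender or UNKNOWN,
            age_group=age_group(p.age),
            bmi_group=bmi_class(p.height_cm, p.weight_kg, collapse_obese=True),
            bmi_group_fine=bmi_class(p.height_cm, p.weight_kg, collapse_obese=False),
            diagnosis=p.diabetes_type or UNKNOWN,
            recent=recently_diagnosed(p),
            insulin=("insulin" if flags.any_insulin
                     else "noninsulin" if p.medications else UNKNOWN),
            bg_control=fasting_bg_control(sub),
            n_modules_used=int(module_counts.get(member.user_id, 0)),
        )
        row = vars(fv) | vars(flags)
        row["tir_control"] = tir_control(sub)
        rows.append(row)
    return pd.DataFrame(rows)


def descriptives(features: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics summary: per-level counts and percentages
    over known values, plus the unknown tally per characteristic."""
    n = len(features)
    out = []
    for col in ("gender", "age_group", "bmi_group_fine", "diagnosis",
                "recent", "insulin", "bg_control", "tir_control"):
        known = features[features[col] != UNKNOWN][col]
        n_unknown = int((features[col] == UNKNOWN).sum())
        counts = known.value_counts()
        for level, cnt in counts.items():
            out.append({
                "characteristic": col, "level": level, "n": int(cnt),
                "pct_of_known": round(100.0 * cnt / len(known), 2) if len(known) else np.nan,
                "n_unknown": n_unknown, "n_total": n,
            })
    counts = features["n_modules_used"].value_counts().sort_index()
    for k, cnt in counts.items():
        out.append({"characteristic": "n_modules_used", "level": str(k),
                    "n": int(cnt), "pct_of_known": round(100.0 * cnt / n, 2),
                    "n_unknown": 0, "n_total": n})
    return pd.DataFrame(out)
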