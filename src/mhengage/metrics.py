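"""The six-metric user-engagement suite on active-day sets.

Engagement of a user with an app module over a fixed observation window
(default 180 days) is summarised by:

* **user activity ratio (UAR)** — active days / potentially active days,
  with the denominator either the full window (``uar_180``), the user's
  longevity (``uar_longevity``) or their persistence span
  (``uar_persistence``);
* **activity delay** — days from consent to first active day;
* **longevity** — inclusive span from first to last active day;
* **persistence** — days until the first discontinuation, where
  discontinuation is a run of more than ``gap`` consecutive inactive days
  (window length if the user never discontinues);
* **recency** — mean number of days between consecutive active days;
* **regularity** — coefficient of variation of those inter-active-day
  gaps (unitless, so modules with different cadences are comparable).

All operations take an *active-day set*: strictly increasing 1-based day
indices inside the window, as produced by :func:`mhengage.events.active_days`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortMember
from .events import MODULES, active_days

__all__ = [
    "GapThreshold",
    "EngagementMetrics",
    "uar",
    "activity_delay",
    "longevity",
    "persistence",
    "recency",
    "regularity",
    "derive_gap_threshold",
    "compute_metrics",
    "metrics_table",
    "WEEKLY_WINDOW",
]

WEEKLY_WINDOW = 26  # ceil(180 / 7) one-week bins


@dataclass(frozen=True)
class GapThreshold:
    """Permissible inactivity gap defining discontinuation.

    The study value is 28 days, derived as the 0.9 quantile of per-user
    mean inter-active-day gaps.
    """

    value_days: int = 28
    quantile: float = 0.9

    def __post_init__(self) -> None:
        if self.value_days < 1:
            raise ValueError("value_days must be >= 1")


@dataclass
class EngagementMetrics:
    user_id: str
    module: str  # module name or "any"
    n_active_days: int
    uar_180: float
    uar_longevity: float
    uar_persistence: float
    activity_delay: int
    longevity: int
    persistence: int
    recency: float | None
    regularity: float | None


def _check_active(active: Sequence[int]) -> list[int]:
    days = sorted(set(int(d) for d in active))
    if days and days[0] < 1:
        raise ValueError("day indices must be >= 1")
    return days


def uar(active: Iterable[int], denominator_days: int) -> float:
    """Active days divided by potentially active days."""
    if denominator_days < 1:
        raise ValueError("denominator_days must be >= 1")
    return len(set(active)) / denominator_days


def activity_delay(consent: date, first_active: date) -> int:
    """Days from consent to first active day (same day -> 0)."""
    delta = (first_active - consent).days
    if delta < 0:
        raise ValueError("first active day precedes consent")
    return delta


def longevity(active: Sequence[int]) -> int:
    """Inclusive span from first to last active day (single day -> 1)."""
    days = _check_active(active)
    if not days:
        raise ValueError("longevity undefined for an empty active-day set")
    return days[-1] - days[0] + 1


def persistence(active: Sequence[int], gap: GapThreshold | int, window_len: int = 180) -> int:
    """Days from the first active day until the first discontinuation.

    Discontinuation is a run of more than ``gap`` consecutive inactive days
    (between two active days, ``next - prev - 1`` silent days; at the end of
    the window, ``window_len - last`` silent days).  Without a qualifying
    gap the user persisted through the whole window and the value is
    ``window_len``.
    """
    days = _check_active(active)
    if not days:
        raise ValueError("persistence undefined for an empty active-day set")
    g = gap.value_days if isinstance(gap, GapThreshold) else int(gap)
    first = days[0]
    for prev, nxt in zip(days, days[1:]):
        if nxt - prev - 1 > g:
            return prev - first + 1
    if window_len - days[-1] > g:  # trailing silence also discontinues
        return days[-1] - first + 1
    return window_len


def _gaps(days: list[int]) -> np.ndarray:
    return np.diff(np.asarray(days))


def recency(active: Sequence[int]) -> float | None:
    """Mean days between consecutive active days; None below 2 active days."""
    days = _check_active(active)
    if len(days) < 2:
        return None
    return float(np.mean(_gaps(days)))


def regularity(active: Sequence[int]) -> float | None:
    """Coefficient of variation (sample SD / mean) of inter-active-day gaps.

    Needs at least two gaps (three active days); SD uses the n-1
    denominator.
    """
    days = _check_active(active)
    if len(days) < 3:
        return None
    gaps = _gaps(days)
    mean = float(np.mean(gaps))
    if mean == 0:  # impossible for distinct day indices, kept for safety
        return None
    return float(np.std(gaps, ddof=1) / mean)


def derive_gap_threshold(per_user_mean_gaps: Sequence[float], quantile: float = 0.9) -> GapThreshold:
    """Permissible-gap threshold from the cohort's inter-entry cadence.

    Takes per-user mean gaps (users with >= 2 active days), interpolates the
    requested quantile linearly and rounds up to whole days.
    """
    vals = np.asarray(list(per_user_mean_gaps), dtype=float)
    if vals.size == 0:
        raise ValueError("no per-user mean gaps supplied")
    q = float(np.quantile(vals, quantile, method="linear"))
    return GapThreshold(value_days=int(math.ceil(q)), quantile=quantile)


def compute_metrics(
    user_id: str,
    module: str,
    active: Sequence[int],
    consent: date,
    first_active_date: date,
    gap: GapThreshold | int,
    window_len: int = 180,
) -> EngagementMetrics:
    """Full metric vector for one user x module active-day (or week) set.

    ``first_active_date`` is the calendar date of the first entry, so the
    activity delay stays on the day scale even when the indices are weekly
    bins.
    """
    days = _check_active(active)
    if not days:
        raise ValueError("metrics undefined for an empty active-day set")
    if days[-1] > window_len:
        raise ValueError("active day outside the window")
    lon = longevity(days)
    per = persistence(days, gap, window_len)
    span_end = days[0] + per - 1
    n_in_span = sum(1 for d in days if d <= span_end)
    return EngagementMetrics(
        user_id=user_id,
        module=module,
        n_active_days=len(days),
        uar_180=uar(days, window_len),
        uar_longevity=uar(days, lon),
        uar_persistence=n_in_span / per,
        activity_delay=activity_delay(consent, first_active_date),
        longevity=lon,
        persistence=per,
        recency=recency(days),
        regularity=regularity(days),
    )


def to_weekly(active: Sequence[int]) -> list[int]:
    """Collapse day indices to 1-based week indices (ceil(day / 7))."""
    return sorted({(d - 1) // 7 + 1 for d in _check_active(active)})


def metrics_table(
    events: pd.DataFrame,
    cohort: Sequence[CohortMember],
    gap: GapThreshold | int,
    weekly: bool = False,
    timestamp: str = "entry",
) -> pd.DataFrame:
    """One metric row per user x initiated module, plus a pooled "any" row.

    The "any" row deduplicates days across modules: a day is active if any
    module has an entry.  With ``weekly=True`` day indices are replaced by
    week indices 1..26 throughout (metrics then carry week units) and the
    gap threshold is interpreted in weeks.
    """
    # dedupe to one row per (user, module, calendar day) once, then group
    col = "entry_time" if timestamp == "entry" else "event_time"
    day_table = (
        events[["user_id", "module"]]
        .assign(day=events[col].dt.normalize())
        .drop_duplicates()
    )
    by_user = {uid: sub for uid, sub in day_table.groupby("user_id")}

    rows = []
    for member in cohort:
        window = member.window
        wlen = WEEKLY_WINDOW if weekly else window.length_days
        pooled: set[int] = set()
        user_days = by_user.get(member.user_id)

        def _first_date(days: Sequence[int]) -> date:
            return window.anchor + timedelta(days=days[0] - 1)

        def _module_days(module: str) -> list[int]:
            if user_days is None:
                return []
            sub = user_days[user_days["module"] == module]
            idx = (sub["day"] - pd.Timestamp(window.anchor)).dt.days + 1
            return sorted(int(d) for d in idx if 1 <= d <= window.length_days)

        for module in MODULES:
            days = _module_days(module.value)
            if not days:
                continue
            pooled.update(days)
            idx = to_weekly(days) if weekly else days
            rows.append(compute_metrics(member.user_id, module.value, idx,
                                        member.consent_date, _first_date(days), gap, wlen))
        if pooled:
            days = sorted(pooled)
            idx = to_weekly(days) if weekly else days
            rows.append(compute_metrics(member.user_id, "any", idx,
                                        member.consent_date, _first_date(days), gap, wlen))
    df = pd.DataFrame([vars(r) for r in rows])
    if df.empty:
        df = pd.DataFrame(columns=[f.name for f in
                                   EngagementMetrics.__dataclass_fields__.values()])
    return df
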