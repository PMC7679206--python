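"""Dropout and uptake summaries: survival curves, event matrices, monthly
active users.

The survival curve for a module re-indexes each user's activity so that
day 1 is their first interaction with that module; a user "survives" to
day d if their last active day (re-indexed) is on or after d — i.e. the
curve at d is the share of users whose longevity reaches d.  Event
matrices give the raw user x day activity pattern behind the curves, and
the monthly series counts distinct active users per calendar month on the
uncensored event log (demand over calendar time).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortMember
from .events import Module, active_days

__all__ = ["survival_curve", "monthly_active", "event_matrix"]


def survival_curve(metrics: pd.DataFrame, module: str,
                   window_len: int = 180) -> pd.DataFrame:
    """Fraction of module users still active on each (re-indexed) day.

    Columns: module, day (1..window_len), fraction_active.  Starts at 1 and
    is non-increasing; its discrete area equals the mean longevity.
    """
    sub = metrics[metrics["module"] == module]
    if sub.empty:
        raise ValueError(f"no users for module {module!r}")
    last = sub["longevity"].to_numpy()  # re-indexed last active day
    days = np.arange(1, window_len + 1)
    frac = (last[None, :] >= days[:, None]).mean(axis=1)
    return pd.DataFrame({"module": module, "day": days, "fraction_active": frac})


def monthly_active(events: pd.DataFrame, timestamp: str = "entry") -> pd.DataFrame:
    """Distinct active users per calendar month and module.

    Months without activity inside the observed span are reported with a
    zero count, so trends are not distorted by missing rows.
    """
    if events.empty:
        return pd.DataFrame(columns=["module", "month", "n_users"])
    col = "entry_time" if timestamp == "entry" else "event_time"
    df = events.assign(month=events[col].dt.to_period("M"))
    counts = df.groupby(["module", "month"])["user_id"].nunique()
    months = pd.period_range(df["month"].min(), df["month"].max(), freq="M")
    rows = []
    for module in sorted(df["module"].unique()):
        for month in months:
            rows.append({
                "module": module,
                "month": str(month),
                "n_users": int(counts.get((module, month), 0)),
            })
    return pd.DataFrame(rows)


def event_matrix(events: pd.DataFrame, cohort: Sequence[CohortMember],
                 module: str | Module, timestamp: str = "entry") -> pd.DataFrame:
    """Sparse user x day activity triplets for one module.

    Rows (``user_rank``) are ordered by each user's first module-active
    day; one triplet per active day, so per-user row sums equal their
    active-day counts.  Columns: module, user_rank, user_id, day.
    """
    mod = module.value if isinstance(module, Module) else module
    sub_mod = events[events["module"] == mod]
    by_user = {uid: sub for uid, sub in sub_mod.groupby("user_id")}
    per_user: list[tuple[int, str, list[int]]] = []
    for member in cohort:
        user_events = by_user.get(member.user_id)
        if user_events is None:
            continue
        days = active_days(user_events, member.user_id, mod, member.window,
                           timestamp=timestamp)
        if days:
            per_user.append((days[0], member.user_id, days))
    per_user.sort(key=lambda t: (t[0], t[1]))
    rows = [
        {"module": mod, "user_rank": rank, "user_id": uid, "day": d}
        for rank, (_, uid, days) in enumerate(per_user, start=1)
        for d in days
    ]
    return pd.DataFrame(rows, columns=["module", "user_rank", "user_id", "day"])
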