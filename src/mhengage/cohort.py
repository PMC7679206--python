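"""Censoring and inclusion rules defining the analyzable sample.

Users enter the analysis only if their whole observation window (default
180 days from initiation) fits inside the data extract — otherwise their
engagement would be right-censored and activity ratios biased downward.
The attrition narrative (consented → initiated → included) is reported at
every stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd

from .events import DateWindow, Module, UserProfile

__all__ = ["AnchorPolicy", "CohortMember", "CohortReport", "build_cohort",
           "initiation_fraction", "write_cohort", "read_cohort"]

# Window anchoring: "initiation" starts the window at the user's first
# active day (activity assessment); "consent" starts it at the consent date
# (delay semantics).
AnchorPolicy = str
ANCHOR_POLICIES = ("initiation", "consent")


@dataclass
class CohortMember:
    user_id: str
    consent_date: date
    initiation_date: date
    window: DateWindow
    modules_initiated: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.initiation_date < self.consent_date:
            raise ValueError(
                f"user {self.user_id}: initiation {self.initiation_date} "
                f"precedes consent {self.consent_date}"
            )


@dataclass
class CohortReport:
    n_consented: int
    n_initiated: int
    n_included: int


def build_cohort(
    profiles: Sequence[UserProfile],
    events: pd.DataFrame,
    data_end: date,
    policy: AnchorPolicy = "initiation",
    window_length: int = 180,
    timestamp: str = "entry",
) -> tuple[list[CohortMember], CohortReport]:
    """Select users whose full observation window is covered by the extract.

    A user is *initiated* if they have at least one event; they are
    *included* if in addition the window (anchored per ``policy``) ends on
    or before ``data_end``.  ``modules_initiated`` holds the modules with at
    least one entry inside the window.
    """
    if policy not in ANCHOR_POLICIES:
        raise ValueError(f"unknown anchor policy {policy!r}")
    consent = {p.user_id: p.consent_date for p in profiles}
    col = "entry_time" if timestamp == "entry" else "event_time"

    members: list[CohortMember] = []
    n_initiated = 0
    if not events.empty:
        # one row per (user, module, day): enough for first-event and
        # window-membership logic, and much smaller than the raw log
        day_table = (events[["user_id", "module"]]
                     .assign(day=events[col].dt.normalize())
                     .drop_duplicates())
        per_user_first = day_table.groupby("user_id")["day"].min()
        by_user = {uid: sub for uid, sub in day_table.groupby("user_id")}
        for user_id, first_ts in per_user_first.items():
            if user_id not in consent:
                continue  # no consent record: not analyzable
            n_initiated += 1
            initiation = first_ts.date()
            anchor = initiation if policy == "initiation" else consent[user_id]
            window = DateWindow(anchor=anchor, length_days=window_length)
            if window.end > data_end:
                continue
            sub = by_user[user_id]
            in_win = sub[
                (sub["day"] >= pd.Timestamp(window.anchor))
                & (sub["day"] <= pd.Timestamp(window.end))
            ]
            modules = {Module(m) for m in in_win["module"].unique()}
            members.append(
                CohortMember(
                    user_id=str(user_id),
                    consent_date=consent[user_id],
                    initiation_date=initiation,
                    window=window,
                    modules_initiated=modules,
                )
            )
    report = CohortReport(
        n_consented=len(profiles), n_initiated=n_initiated, n_included=len(members)
    )
    return members, report


def initiation_fraction(n_initiated: int, n_consented: int) -> float:
    """Share of consenting users who went on to use the app, in percent
    rounded to 2 decimals (also reused for any count/denominator share)."""
    if n_consented <= 0:
        raise ValueError("n_consented must be positive")
    if n_initiated > n_consented:
        raise ValueError("n_initiated cannot exceed n_consented")
    return round(100.0 * n_initiated / n_consented, 2)


def write_cohort(members: Sequence[CohortMember], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["user_id", "consent_date", "initiation_date",
                        "window_start", "window_end", "modules_initiated"],
        )
        writer.writeheader()
        for m in members:
            writer.writerow(
                {
                    "user_id": m.user_id,
                    "consent_date": m.consent_date.isoformat(),
                    "initiation_date": m.initiation_date.isoformat(),
                    "window_start": m.window.anchor.isoformat(),
                    "window_end": m.window.end.isoformat(),
                    "modules_initiated": ";".join(
                        sorted(mod.value for mod in m.modules_initiated)
                    ),
                }
            )


def read_cohort(path: str | Path) -> list[CohortMember]:
    members = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            anchor = date.fromisoformat(row["window_start"])
            end = date.fromisoformat(row["window_end"])
            members.append(
                CohortMember(
                    user_id=row["user_id"],
                    consent_date=date.fromisoformat(row["consent_date"]),
                    initiation_date=date.fromisoformat(row["initiation_date"]),
                    window=DateWindow(anchor=anchor, length_days=(end - anchor).days + 1),
                    modules_initiated={
                        Module(m) for m in row["modules_initiated"].split(";") if m
                    },
                )
            )
    return members
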