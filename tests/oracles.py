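"""Independent brute-force reference implementations for the metric suite.

These deliberately avoid the package's code paths: each metric is computed
by literal day-by-day scanning of a boolean activity array, so agreement
with the library is a genuine two-route check.
"""

from __future__ import annotations

import statistics


def bf_active_days(dates: list, anchor, length: int) -> list[int]:
    """O(days) scan: day d is active iff some event date equals anchor+(d-1)."""
    out = []
    for d in range(1, length + 1):
        target = anchor.toordinal() + (d - 1)
        if any(dt.toordinal() == target for dt in dates):
            out.append(d)
    return out


def bf_uar(active: set[int], denom: int) -> float:
    return len(active) / denom


def bf_longevity(active: set[int]) -> int:
    return max(active) - min(active) + 1


def bf_persistence(active: set[int], gap: int, window_len: int) -> int:
    """Walk the window day by day counting consecutive inactive runs."""
    first = min(active)
    last_active = first
    run = 0
    for day in range(first + 1, window_len + 1):
        if day in active:
            last_active = day
            run = 0
        else:
            run += 1
            if run > gap:
                return last_active - first + 1
    return window_len


def bf_recency(active: set[int]) -> float | None:
    days = sorted(int(d) for d in active)
    if len(days) < 2:
        return None
    gaps = [b - a for a, b in zip(days, days[1:])]
    return sum(gaps) / len(gaps)


def bf_regularity(active: set[int]) -> float | None:
    days = sorted(int(d) for d in active)
    if len(days) < 3:
        return None
    gaps = [b - a for a, b in zip(days, days[1:])]
    mean = sum(gaps) / len(gaps)
    if mean == 0:
        return None
    return statistics.stdev(gaps) / mean


def bf_uar_longevity(active: set[int]) -> float:
    return len(active) / bf_longevity(active)


def bf_uar_persistence(active: set[int], gap: int, window_len: int) -> float:
    per = bf_persistence(active, gap, window_len)
    first = min(active)
    in_span = sum(1 for d in active if d <= first + per - 1)
    return in_span / per


def bf_metric_suite(active: set[int], gap: int, window_len: int) -> dict:
    return {
        "n_active_days": len(active),
        "uar_180": bf_uar(active, window_len),
        "uar_longevity": bf_uar_longevity(active),
        "uar_persistence": bf_uar_persistence(active, gap, window_len),
        "longevity": bf_longevity(active),
        "persistence": bf_persistence(active, gap, window_len),
        "recency": bf_recency(active),
        "regularity": bf_regularity(active),
    }
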