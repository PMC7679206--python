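"""Engagement metric suite: worked examples, oracle equality, invariants."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhengage.cohort import build_cohort
from mhengage.events import EventRecord, Module, UserProfile, events_to_frame
from mhengage.metrics import (GapThreshold, compute_metrics,
                              derive_gap_threshold, longevity, metrics_table,
                              persistence, recency, regularity, to_weekly, uar)

from oracles import bf_metric_suite

GAP = GapThreshold(28)


class TestSingleMetrics:
    def test_uar_examples(self):
        assert uar({1, 5, 9}, 180) == pytest.approx(3 / 180)
        assert uar(set(range(1, 181)), 180) == 1.0
        with pytest.raises(ValueError):
            uar({1}, 0)

    @pytest.mark.parametrize("active, expected", [
        (range(3, 151), 148),
        ({42}, 1),
        ({1, 180}, 180),  # printed maximum
    ])
    def test_longevity(self, active, expected):
        assert longevity(set(active)) == expected

    def test_longevity_empty_errors(self):
        with pytest.raises(ValueError):
            longevity(set())

    @pytest.mark.parametrize("active, expected", [
        ({1, 2, 3, 40, 41}, 3),      # 36 silent days after day 3
        (set(range(1, 181)), 180),   # never discontinues
        ({1, 160}, 1),               # immediate discontinuation
        ({1, 31}, 1),                # 29 silent days: over the threshold
        ({1, 30}, 30),               # 28-day gap permissible, but 150 trailing
                                     # silent days end the span at day 30
        ({150}, 1),                  # trailing 30 silent days discontinue
        ({160}, 180),                # trailing 20 silent days do not
    ])
    def test_persistence_gap_rule(self, active, expected):
        assert persistence(active, GAP, 180) == expected

    def test_recency(self):
        assert recency({1, 5, 9}) == 4.0
        assert recency({7}) is None

    def test_regularity(self):
        assert regularity({1, 5, 9}) == 0.0
        # gaps {2, 6}: sd with n-1 = sqrt(8), mean 4
        assert regularity({1, 3, 9}) == pytest.approx(np.sqrt(8) / 4)
        assert regularity({1, 5}) is None

    def test_periodic_user_perfectly_regular(self):
        for period in (2, 7, 13):
            days = set(range(1, 180, period))
            assert regularity(days) == 0.0

    def test_recency_matches_brute_force(self, rng):
        for _ in range(200):
            days = set(rng.choice(180, size=rng.integers(2, 40),
                                  replace=False) + 1)
            suite = bf_metric_suite(days, 28, 180)
            assert recency(days) == pytest.approx(suite["recency"])
            if len(days) >= 3:
                assert regularity(days) == pytest.approx(suite["regularity"])


class TestGapThreshold:
    def test_constant_list(self):
        assert derive_gap_threshold([5, 5, 5, 5]).value_days == 5

    def test_interpolated_quantile_is_ceiled(self):
        # 0.9 quantile of 1..100 interpolates to 90.1 -> 91 days
        assert derive_gap_threshold(list(range(1, 101))).value_days == 91

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            derive_gap_threshold([])


class TestOracleEquivalence:
    def _compare(self, days: set, window_len: int, gap: int):
        days = {int(d) for d in days}
        m = compute_metrics("u", "mod", sorted(days), date(2019, 1, 1),
                            date(2019, 1, 1) + timedelta(days=min(days) - 1),
                            GapThreshold(gap), window_len)
        bf = bf_metric_suite(days, gap, window_len)
        assert m.n_active_days == bf["n_active_days"]
        assert m.uar_180 == bf["uar_180"]
        assert m.uar_longevity == bf["uar_longevity"]
        assert m.uar_persistence == bf["uar_persistence"]
        assert m.longevity == bf["longevity"]
        assert m.persistence == bf["persistence"]
        assert m.recency == bf["recency"]
        assert (m.regularity == pytest.approx(bf["regularity"])
                if bf["regularity"] is not None else m.regularity is None)

    def test_exhaustive_small_windows(self):
        """All nonempty active-day subsets of a 10-day window, gaps 2 and 3."""
        for gap in (2, 3):
            for bits in range(1, 2 ** 10):
                days = {d + 1 for d in range(10) if bits >> d & 1}
                self._compare(days, 10, gap)

    def test_random_subsets_full_window(self, rng):
        for _ in range(500):
            k = int(rng.integers(1, 120))
            days = set(rng.choice(180, size=k, replace=False) + 1)
            self._compare(days, 180, 28)


class TestInvariantsProperty:
    @given(st.sets(st.integers(min_value=1, max_value=180), min_size=1,
                   max_size=90),
           st.integers(min_value=1, max_value=60))
    @settings(max_examples=200, deadline=None)
    def test_uar_bounds_and_persistence_iff_gap(self, days, gap):
        m = compute_metrics("u", "mod", sorted(days), date(2019, 1, 1),
                            date(2019, 1, 1), GapThreshold(gap), 180)
        assert m.uar_180 <= m.uar_longevity <= 1.0
        assert m.uar_persistence <= 1.0
        assert m.n_active_days <= m.longevity
        assert 1 <= m.persistence <= 180
        sorted_days = sorted(days)
        runs = [b - a - 1 for a, b in zip(sorted_days, sorted_days[1:])]
        runs.append(180 - sorted_days[-1])
        assert (m.persistence == 180) == all(r <= gap for r in runs)
        assert (m.recency is None) == (len(days) < 2)
        assert (m.regularity is None) == (len(days) < 3)


class TestMetricsTable:
    def _cohort(self, records):
        profiles = [UserProfile(u, date(2019, 1, 1))
                    for u in {r.user_id for r in records}]
        events = events_to_frame(records)
        members, _ = build_cohort(profiles, events, date(2020, 12, 31))
        return events, members

    def test_single_module_user_pooled_row_identical(self):
        records = [EventRecord("u1", Module.FOOD, datetime(2019, 1, d, 9))
                   for d in (1, 4, 9)]
        events, members = self._cohort(records)
        table = metrics_table(events, members, GAP)
        assert len(table) == 2
        food = table[table["module"] == "food"].iloc[0]
        pooled = table[table["module"] == "any"].iloc[0]
        for col in ("n_active_days", "uar_180", "longevity", "persistence",
                    "recency", "regularity"):
            assert food[col] == pooled[col]

    def test_weekly_binning(self):
        assert to_weekly([1, 8, 15]) == [1, 2, 3]
        records = [EventRecord("u1", Module.FOOD, datetime(2019, 1, d, 9))
                   for d in (1, 8, 15)]
        events, members = self._cohort(records)
        table = metrics_table(events, members, GapThreshold(4), weekly=True)
        food = table[table["module"] == "food"].iloc[0]
        assert food["n_active_days"] == 3
        assert food["recency"] == 1.0
        assert food["uar_180"] == pytest.approx(3 / 26)

    def test_any_row_dedupes_across_modules(self):
        records = [
            EventRecord("u1", Module.FOOD, datetime(2019, 1, 1, 9)),
            EventRecord("u1", Module.EXERCISE, datetime(2019, 1, 1, 18)),
            EventRecord("u1", Module.FOOD, datetime(2019, 1, 3, 9)),
        ]
        events, members = self._cohort(records)
        table = metrics_table(events, members, GAP)
        pooled = table[table["module"] == "any"].iloc[0]
        assert pooled["n_active_days"] == 2

    def test_duplicate_entries_and_order_do_not_matter(self, rng):
        records = [EventRecord("u1", Module.FOOD,
                               datetime(2019, 1, 1) + timedelta(
                                   days=int(d), hours=int(h)))
                   for d, h in zip(rng.integers(0, 60, 40),
                                   rng.integers(1, 23, 40))]
        events, members = self._cohort(records)
        base = metrics_table(events, members, GAP)
        shuffled = events.sample(frac=1, random_state=1).reset_index(drop=True)
        doubled = events_to_frame(
            [r for r in records for _ in range(2)])
        for other in (shuffled, doubled):
            table = metrics_table(other, members, GAP)
            assert table.reset_index(drop=True).equals(base.reset_index(drop=True))

    def test_weekly_active_count_never_exceeds_daily(self, small_cohort):
        events, profiles, truth = small_cohort
        members, _ = build_cohort(profiles, events, truth.config.data_end)
        daily = metrics_table(events, members, GAP)
        weekly = metrics_table(events, members, GAP, weekly=True)
        key = ["user_id", "module"]
        merged = daily.merge(weekly, on=key, suffixes=("_d", "_w"))
        assert (merged["n_active_days_w"] <= merged["n_active_days_d"]).all()

    def test_per_module_mean_uar_tracks_generator(self, small_cohort):
        """Mean daily-window UAR per module stays within Monte-Carlo range of
        the generator's programmed activity levels (high for food/medication
        conditional on persistence, high for device modules overall)."""
        events, profiles, truth = small_cohort
        members, _ = build_cohort(profiles, events, truth.config.data_end)
        table = metrics_table(events, members, GAP)
        means = table.groupby("module")["uar_180"].mean()
        # device modules persist: their full-window UAR dominates manual ones
        assert means["cgm"] > means["medication"]
        assert means["exercise"] > means["food"]
        # manual modules churn fast: low full-window UAR
        assert means["medication"] < 0.2 and means["food"] < 0.2
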