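"""Event-log and profile readers: validation, round trips, active days."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhengage.events import (DateWindow, EventRecord, MealTag, MedicationEntry,
                             MedType, Module, UserProfile, active_days,
                             apply_plausibility, events_to_frame,
                             filter_preconsent, frame_to_events, read_events,
                             read_profiles, write_events, write_profiles)

from oracles import bf_active_days


def _rec(user="u1", module="food", day=1, hour=12, value=None, tag=None):
    return EventRecord(
        user_id=user, module=Module(module),
        entry_time=datetime(2019, 1, day, hour),
        value=value, meal_tag=MealTag(tag) if tag else None,
    )


class TestReadEvents:
    def test_unknown_module_rejected_with_report(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            "user_id,module,event_time,entry_time,value,meal_tag\n"
            "u1,food,,2019-01-01T10:00:00,,\n"
            "u1,steps,,2019-01-01T11:00:00,,\n"
            "u2,bg,,2019-01-02T08:00:00,110,fasting\n"
            "u2,exercise,,2019-01-03T09:00:00,,\n"
        )
        records, report = read_events(p)
        assert len(records) == 3
        assert report.rejected == {"unknown_module": 1}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("user_id,module,event_time,entry_time,value,meal_tag\n")
        records, report = read_events(p)
        assert records == [] and report.n_read == 0

    def test_glucose_modules_require_positive_value(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            "user_id,module,event_time,entry_time,value,meal_tag\n"
            "u1,bg,,2019-01-01T10:00:00,,\n"
            "u1,cgm,,2019-01-01T10:05:00,-5,\n"
        )
        records, report = read_events(p)
        assert records == []
        assert report.rejected["missing_or_nonpositive_glucose"] == 2

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_events(tmp_path / "nope.csv")

    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_round_trip_identity(self, tmp_path, fmt, rng):
        records = []
        for i in range(1000):
            module = Module(list(Module)[rng.integers(5)])
            value = (float(rng.integers(60, 260))
                     if module in (Module.BG, Module.CGM) else None)
            records.append(EventRecord(
                user_id=f"u{rng.integers(40)}", module=module,
                entry_time=datetime(2019, 1, 1) + timedelta(
                    minutes=int(rng.integers(0, 300_000))),
                event_time=None,
                value=value,
                meal_tag=MealTag.FASTING if (module is Module.BG
                                             and rng.random() < 0.3) else None,
            ))
        records.sort(key=lambda r: (r.user_id, r.module.value, r.entry_time))
        path = tmp_path / f"ev.{fmt}"
        write_events(records, path, fmt=fmt)
        back, report = read_events(path, fmt=fmt)
        assert back == records
        assert report.n_rejected == 0

    def test_frame_round_trip(self):
        # the frame view materialises the event-time fallback, so use
        # records with explicit event times for exact inversion
        records = [
            EventRecord("u1", Module.FOOD, datetime(2019, 1, d, 12),
                        event_time=datetime(2019, 1, d, 11))
            for d in (1, 2, 3)
        ]
        assert frame_to_events(events_to_frame(records)) == records


class TestProfiles:
    def test_implausible_age_becomes_absent_user_kept(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("user_id,consent_date,gender,age,height_cm,weight_kg,diabetes_type\n"
                     "u1,2019-01-01,female,104,,,t2d\n")
        profiles, report = read_profiles(p)
        assert len(profiles) == 1
        assert profiles[0].age is None
        assert report.missingness["age"] == 1

    def test_plausible_profile_unchanged(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("user_id,consent_date,gender,age,height_cm,weight_kg,diabetes_type\n"
                     "u1,2019-01-01,male,55,180,81,t1d\n")
        profiles, _ = read_profiles(p)
        assert (profiles[0].height_cm, profiles[0].weight_kg) == (180, 81)

    def test_duplicate_user_fatal(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("user_id,consent_date\nu1,2019-01-01\nu1,2019-01-02\n")
        with pytest.raises(ValueError, match="u1"):
            read_profiles(p)

    def test_injected_implausibles_are_counted(self, tmp_path, rng):
        """Missingness report equals the number of injected bad values."""
        rows = ["user_id,consent_date,gender,age,height_cm,weight_kg,diabetes_type"]
        n_bad_age = n_bad_h = 0
        for i in range(500):
            if rng.random() < 0.1:
                age, n_bad_age = 110, n_bad_age + 1
            else:
                age = 50
            if rng.random() < 0.2:
                h, n_bad_h = 130, n_bad_h + 1
            else:
                h = 170
            rows.append(f"u{i},2019-01-01,male,{age},{h},80,t2d")
        p = tmp_path / "p.csv"
        p.write_text("\n".join(rows) + "\n")
        _, report = read_profiles(p)
        assert report.missingness["age"] == n_bad_age
        assert report.missingness["height_cm"] == n_bad_h

    def test_plausibility_idempotent(self):
        prof = UserProfile("u1", date(2019, 1, 1), age=104.0, height_cm=150.0)
        once = apply_plausibility(prof)
        assert once.age is None and once.height_cm == 150.0
        again = apply_plausibility(once)
        assert vars(again) == vars(once)

    def test_profile_round_trip_with_medications(self, tmp_path):
        meds = [MedicationEntry("metformin", MedType.ORAL, date(2018, 6, 1)),
                MedicationEntry("insulin aspart", MedType.INSULIN,
                                date(2018, 7, 1), is_bolus=True)]
        profiles = [UserProfile("u1", date(2019, 1, 1), gender="female",
                                age=60.0, height_cm=165.0, weight_kg=70.0,
                                diabetes_type="t2d", medications=meds)]
        write_profiles(profiles, tmp_path / "p.csv", tmp_path / "m.csv")
        back, _ = read_profiles(tmp_path / "p.csv", tmp_path / "m.csv")
        assert back == profiles

    def test_bolus_requires_insulin(self):
        with pytest.raises(ValueError):
            MedicationEntry("metformin", MedType.ORAL, date(2018, 1, 1),
                            is_bolus=True)


class TestActiveDays:
    WINDOW = DateWindow(anchor=date(2019, 1, 1), length_days=180)

    def test_same_day_entries_collapse(self):
        records = [_rec(day=5, hour=h) for h in (8, 12, 20)]
        assert active_days(records, "u1", "food", self.WINDOW) == [5]

    def test_window_clipping(self):
        window = DateWindow(anchor=date(2019, 1, 1), length_days=180)
        offsets = [0, 4, 179, 200]
        records = [
            EventRecord("u1", Module.FOOD,
                        datetime(2019, 1, 1, 9) + timedelta(days=o))
            for o in offsets
        ]
        assert active_days(records, "u1", "food", window) == [1, 5, 180]

    def test_no_events_empty(self):
        assert active_days([], "u1", "food", self.WINDOW) == []

    @given(st.lists(st.integers(min_value=-10, max_value=220), max_size=60),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_and_order_invariant(self, offsets, rnd):
        window = DateWindow(anchor=date(2019, 3, 1), length_days=180)
        records = [
            EventRecord("u1", Module.BG,
                        datetime(2019, 3, 1, 10) + timedelta(days=o), value=100.0)
            for o in offsets
        ]
        expected = bf_active_days(
            [r.entry_time.date() for r in records], window.anchor, 180)
        got = active_days(records, "u1", "bg", window)
        assert got == expected
        rnd.shuffle(records)
        assert active_days(records, "u1", "bg", window) == expected
        assert all(1 <= d <= 180 for d in got)
        assert got == sorted(set(got))


def test_preconsent_events_are_dropped():
    profiles = [UserProfile("u1", date(2019, 1, 10))]
    records = [_rec(day=5), _rec(day=10), _rec(day=15)]
    df, n_dropped = filter_preconsent(events_to_frame(records), profiles)
    assert n_dropped == 1
    assert len(df) == 2
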