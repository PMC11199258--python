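import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neoscr as ns
from neoscr.errors import ValidationError


# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate all maximal runs, then look up the
# run that ends the day before evaluation
# ---------------------------------------------------------------------------

def oracle_runs(admin_days):
    days = sorted(admin_days)
    runs, current = [], []
    for d in days:
        if current and d == current[-1] + 1:
            current.append(d)
        else:
            if current:
                runs.append(current)
            current = [d]
    if current:
        runs.append(current)
    return runs


def oracle_consecutive(admin_days, day):
    # the run ending on day-1 is the part of the enclosing maximal run that
    # lies on or before day-1 (administration on/after the evaluation day
    # cannot have influenced the measurement)
    for run in oracle_runs(admin_days):
        if day - 1 in run:
            return min(sum(1 for d in run if d <= day - 1), 5)
    return 0


class TestLagIndicator:
    def test_lag_one_day(self):
        cal = ns.ExposureCalendar.from_records([("X", "ibuprofen", 4)])
        assert ns.lag_indicator(cal, "X", ns.IBUPROFEN, 5) == 1
        assert ns.lag_indicator(cal, "X", ns.IBUPROFEN, 4) == 0

    def test_group_membership(self):
        cal = ns.ExposureCalendar.from_records([("X", "vancomycin", 9)])
        assert ns.lag_indicator(cal, "X", ns.ANTIBIOTICS, 10) == 1
        assert ns.lag_indicator(cal, "X", ns.AMIKACIN, 10) == 0

    def test_empty_calendar(self, empty_calendar):
        assert all(
            ns.lag_indicator(empty_calendar, "X", ns.ALL_DRUGS, d) == 0 for d in range(1, 30)
        )

    def test_day_one_never_exposed(self):
        cal = ns.ExposureCalendar.from_records([("X", "amikacin", 1)])
        assert ns.lag_indicator(cal, "X", ns.AMIKACIN, 1) == 0


class TestConsecutiveDays:
    @pytest.mark.parametrize(
        "admin,day,expected",
        [
            ({3, 4, 5}, 4, 1), ({3, 4, 5}, 5, 2), ({3, 4, 5}, 6, 3), ({3, 4, 5}, 7, 0),
            ({3, 4, 6, 7}, 6, 0), ({3, 4, 6, 7}, 8, 2),
            (set(range(1, 8)), 8, 5),  # 7 uninterrupted days -> capped "5+"
        ],
    )
    def test_run_length_with_lag(self, admin, day, expected):
        cal = ns.ExposureCalendar.from_records([("X", "ibuprofen", d) for d in admin])
        assert ns.consecutive_days(cal, "X", ns.IBUPROFEN, day) == expected

    def test_matches_brute_force_oracle_on_random_calendars(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            admin = set(rng.choice(np.arange(1, 29), size=rng.integers(0, 15), replace=False))
            cal = ns.ExposureCalendar.from_records(
                [("X", "amikacin", int(d)) for d in admin]
            )
            for day in range(1, 30):
                got = ns.consecutive_days(cal, "X", ns.AMIKACIN, day)
                assert got == oracle_consecutive(admin, day), (sorted(admin), day)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(admin=st.sets(st.integers(1, 20), max_size=12), day=st.integers(1, 22))
    def test_lag_equals_nonzero_run(self, admin, day):
        """lag_indicator(day) == [consecutive_days(day) >= 1] for every calendar."""
        cal = ns.ExposureCalendar.from_records([("X", "ibuprofen", d) for d in admin])
        lag = ns.lag_indicator(cal, "X", ns.IBUPROFEN, day)
        assert lag == (ns.consecutive_days(cal, "X", ns.IBUPROFEN, day) >= 1)


class TestCalendarValidation:
    def test_duplicate_triples_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            ns.ExposureCalendar.from_records([("X", "ibuprofen", 3), ("X", "ibuprofen", 3)])

    def test_unknown_drug_rejected(self):
        with pytest.raises(ValidationError, match="gentamicin"):
            ns.ExposureCalendar.from_records([("X", "gentamicin", 3)])

    def test_day_zero_rejected(self):
        with pytest.raises(ValidationError, match=">= 1"):
            ns.ExposureCalendar.from_records([("X", "ibuprofen", 0)])


def demo_row(pid, admission=1, death=None):
    return {"patient_id": pid, "ga_weeks": 27.0, "bw_g": 800, "sex": "F",
            "admission_day": admission, "death_day": death}


class TestApplyExclusions:
    def test_each_reason(self, make_obs_frame, empty_calendar):
        demo = pd.DataFrame([
            demo_row("ok"),
            demo_row("died_early", death=5),
            demo_row("late", admission=15),
            demo_row("no_baseline"),
            demo_row("twin"), demo_row("twin"),
        ])
        obs = make_obs_frame(
            [("ok", 1, 0.6), ("ok", 5, 0.7), ("died_early", 1, 0.6),
             ("late", 16, 0.7), ("no_baseline", 7, 0.7), ("twin", 1, 0.6)]
        )
        demo_f, obs_f, cal_f, log = ns.apply_exclusions(demo, obs, empty_calendar)
        assert log.disposition == {
            "ok": "included", "died_early": "early_death", "late": "late_referral",
            "no_baseline": "insufficient_baseline", "twin": "duplicate",
        }
        assert set(demo_f["patient_id"]) == {"ok"}
        assert set(obs_f["patient_id"]) == {"ok"}
        assert log.counts["included"] + sum(
            log.counts[r] for r in ("duplicate", "early_death", "late_referral", "insufficient_baseline")
        ) == 5  # every input patient accounted for exactly once

    def test_priority_order(self, make_obs_frame, empty_calendar):
        # a duplicated patient who also died early is logged as duplicate
        demo = pd.DataFrame([demo_row("d", death=3), demo_row("d", death=3)])
        obs = make_obs_frame([("d", 1, 0.6)])
        *_, log = ns.apply_exclusions(demo, obs, empty_calendar)
        assert log.disposition["d"] == "duplicate"

    def test_death_on_day_seven_counts_as_late_death_and_stays(self, make_obs_frame, empty_calendar):
        demo = pd.DataFrame([demo_row("p", death=7)])
        obs = make_obs_frame([("p", 1, 0.6)])
        *_, log = ns.apply_exclusions(demo, obs, empty_calendar)
        assert log.disposition["p"] == "included"

    def test_min_baseline_config(self, make_obs_frame, empty_calendar):
        demo = pd.DataFrame([demo_row("p")])
        obs = make_obs_frame([("p", 2, 0.6)])
        *_, log = ns.apply_exclusions(
            demo, obs, empty_calendar, ns.ExclusionConfig(min_baseline_obs=2)
        )
        assert log.disposition["p"] == "insufficient_baseline"

    def test_idempotent(self, make_obs_frame, empty_calendar):
        demo = pd.DataFrame([demo_row("ok"), demo_row("died", death=2)])
        obs = make_obs_frame([("ok", 1, 0.6), ("died", 1, 0.5)])
        demo1, obs1, cal1, _ = ns.apply_exclusions(demo, obs, empty_calendar)
        demo2, obs2, _, log2 = ns.apply_exclusions(demo1, obs1, cal1)
        pd.testing.assert_frame_equal(demo1, demo2)
        pd.testing.assert_frame_equal(obs1, obs2)
        assert log2.counts["included"] == 1

    def test_missing_columns(self, make_obs_frame, empty_calendar):
        demo = pd.DataFrame({"patient_id": ["p"]})
        with pytest.raises(ValidationError, match="missing columns"):
            ns.apply_exclusions(demo, make_obs_frame([]), empty_calendar)


class TestRestrictWindow:
    def test_boundary_inclusive_at_28(self, make_obs_frame):
        obs = make_obs_frame([("a", 2, 0.6), ("a", 28, 0.7), ("a", 29, 0.8)])
        kept, removed = ns.restrict_window(obs)
        assert kept["pna_day"].tolist() == [2, 28]
        assert removed == 1

    def test_empty_input(self, make_obs_frame):
        kept, removed = ns.restrict_window(make_obs_frame([]))
        assert kept.empty and removed == 0

    def test_42_day_series(self):
        params = ns.SimParams(n_patients=10, day_range=(1, 42), seed=3)
        cohort = ns.simulate_cohort(params)
        kept, removed = ns.restrict_window(cohort.observations, max_day=28)
        assert (kept["pna_day"] <= 28).all()
        assert removed == int((cohort.observations["pna_day"] > 28).sum())
        assert len(kept) + removed == len(cohort.observations)
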