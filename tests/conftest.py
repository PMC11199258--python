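import pandas as pd
import pytest

import neoscr as ns


@pytest.fixture
def ref3():
    """Three-day reference table with easy hand arithmetic."""
    return ns.ReferenceTable({1: 0.60, 2: 0.75, 3: 0.85})


@pytest.fixture
def empty_calendar():
    return ns.ExposureCalendar()


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient default-parameter cohort shared by cheap tests."""
    return ns.simulate_cohort(ns.SimParams(n_patients=40, seed=11))


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    return ns.score_cohort(
        small_cohort.observations, small_cohort.reference_table, small_cohort.calendar
    )


def make_obs(rows):
    """rows: iterable of (patient_id, pna_day, scr_mg_dl)."""
    return pd.DataFrame(rows, columns=["patient_id", "pna_day", "scr_mg_dl"])


@pytest.fixture
def make_obs_frame():
    return make_obs
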