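import pandas as pd
import pytest

from cadphen import (
    Cohort,
    SimulationConfig,
    default_codelist,
    simulate_all,
)


def make_cohort(
    participants=(),
    diagnoses=(),
    procedures=(),
    deaths=(),
    self_reports=(),
) -> Cohort:
    """Build a Cohort directly from row tuples (test helper).

    participants: (pid, enrol_date, sex, age)
    diagnoses: (pid, code_system, code, position, event_date)
    procedures: (pid, code, event_date)
    deaths: (pid, death_date, code, role)
    self_reports: (pid, category, item_code)
    """
    part = pd.DataFrame(
        list(participants), columns=["pid", "enrol_date", "sex", "age_at_enrol"]
    )
    part["enrol_date"] = pd.to_datetime(part["enrol_date"])
    dx = pd.DataFrame(
        list(diagnoses), columns=["pid", "code_system", "code", "position", "event_date"]
    )
    dx["event_date"] = pd.to_datetime(dx["event_date"]) if len(dx) else dx["event_date"]
    proc = pd.DataFrame(
        [(p, "OPCS4", c, d) for p, c, d in procedures],
        columns=["pid", "code_system", "code", "event_date"],
    )
    proc["event_date"] = pd.to_datetime(proc["event_date"]) if len(proc) else proc["event_date"]
    dth = pd.DataFrame(
        [(p, d, "ICD10", c, r) for p, d, c, r in deaths],
        columns=["pid", "death_date", "code_system", "code", "role"],
    )
    dth["death_date"] = pd.to_datetime(dth["death_date"]) if len(dth) else dth["death_date"]
    sr = pd.DataFrame(list(self_reports), columns=["pid", "category", "item_code"])
    return Cohort(part, dx, proc, dth, sr)


@pytest.fixture(scope="session")
def codelist():
    return default_codelist()


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic biobank shared by read-only tests."""
    return simulate_all(SimulationConfig(n=5000, seed=11))


@pytest.fixture
def tiny_cohort():
    """Five hand-built participants covering each branch of the hierarchy."""
    return make_cohort(
        participants=[
            ("P1", "2007-01-01", "male", 55),    # prevalent MI
            ("P2", "2008-06-15", "female", 60),  # incident CAD (procedure)
            ("P3", "2009-03-01", "male", 45),    # self-report MI
            ("P4", "2006-05-20", "female", 50),  # never CAD (died, non-CAD cause)
            ("P5", "2010-02-02", "male", 41),    # no CAD
        ],
        diagnoses=[("P1", "ICD10", "I214", "primary", "2004-05-02")],
        procedures=[("P2", "K491", "2012-07-04")],
        deaths=[("P4", "2014-10-10", "C349", "underlying")],
        self_reports=[("P3", "illness", "heart_attack")],
    )
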