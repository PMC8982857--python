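import numpy as np
import pandas as pd
import pytest

from cadphen import (
    AlgorithmConfig,
    CodeSystem,
    EventSource,
    PhenotypeLabel,
    PhenotypeTag,
    QualifyingEvent,
    SimulationConfig,
    aggregate_all_cad,
    classify_participant,
    default_codelist,
    run_algorithm,
    simulate_cohort,
    summarize_baseline,
)
from cadphen.phenotyper import HIERARCHY_STEP

from conftest import make_cohort


def ev(pid, tag, date, source=EventSource.hospital_dx, code="I214"):
    date = None if date is None else pd.Timestamp(date)
    return QualifyingEvent(pid, PhenotypeTag(tag), date, source, code)


PART = {"pid": "P1", "enrol_date": "2007-01-01"}


class TestClassifyParticipant:
    def test_mi_before_enrolment_is_prevalent(self):
        out = classify_participant([ev("P1", "MI", "2004-05-02")], PART)
        assert out["label"] == PhenotypeLabel.prevalent_MI
        assert out["qualifying_date"] == pd.Timestamp("2004-05-02")

    def test_mi_step_precedes_cad_step(self):
        events = [
            ev("P1", "CAD_noMI", "2005-01-01", code="I251"),
            ev("P1", "MI", "2010-01-01"),
        ]
        out = classify_participant(events, PART)
        assert out["label"] == PhenotypeLabel.incident_MI

    def test_both_sides_default_resolution_is_incident(self):
        events = [
            ev("P1", "MI", "2004-05-02"),
            ev("P1", "MI", "2012-03-01"),
            ev("P1", "MI", "2010-01-01"),
        ]
        out = classify_participant(events, PART)
        assert out["label"] == PhenotypeLabel.incident_MI
        # dated at the earliest post-enrolment event
        assert out["qualifying_date"] == pd.Timestamp("2010-01-01")

    def test_both_sides_prevalent_resolution(self):
        cfg = AlgorithmConfig(both_prevalent_and_incident_resolution="prevalent")
        events = [ev("P1", "MI", "2004-05-02"), ev("P1", "MI", "2010-01-01")]
        out = classify_participant(events, PART, config=cfg)
        assert out["label"] == PhenotypeLabel.prevalent_MI
        assert out["qualifying_date"] == pd.Timestamp("2004-05-02")

    @pytest.mark.parametrize(
        "boundary,expected",
        [("prevalent", PhenotypeLabel.prevalent_MI), ("incident", PhenotypeLabel.incident_MI)],
    )
    def test_event_on_enrolment_date_boundary(self, boundary, expected):
        cfg = AlgorithmConfig(on_enrolment_date_is=boundary)
        out = classify_participant([ev("P1", "MI", "2007-01-01")], PART, config=cfg)
        assert out["label"] == expected

    def test_selfreport_heart_attack_is_sr_mi(self):
        out = classify_participant(
            [], PART, [{"pid": "P1", "category": "illness", "item_code": "heart_attack"}]
        )
        assert out["label"] == PhenotypeLabel.sr_MI
        assert out["qualifying_date"] is None

    def test_selfreport_angina_is_sr_cad(self):
        out = classify_participant(
            [], PART, [{"pid": "P1", "category": "illness", "item_code": "angina"}]
        )
        assert out["label"] == PhenotypeLabel.sr_CAD_noMI

    def test_ehr_cad_beats_selfreport_mi(self):
        out = classify_participant(
            [ev("P1", "CAD_noMI", "2010-06-01", code="I251")],
            PART,
            [{"pid": "P1", "category": "illness", "item_code": "heart_attack"}],
        )
        assert out["label"] == PhenotypeLabel.incident_CAD_noMI

    def test_selfreport_procedure_is_prevalent_cad_anchored_at_enrolment(self):
        out = classify_participant(
            [ev("P1", "CAD_noMI", None, source=EventSource.selfreport_proc, code="cabg")],
            PART,
        )
        assert out["label"] == PhenotypeLabel.prevalent_CAD_noMI
        assert out["qualifying_date"] == pd.Timestamp("2007-01-01")
        assert out["source"] == "selfreport_proc"

    def test_no_events_dead_is_never_cad(self):
        out = classify_participant([], {**PART, "death_date": "2012-01-01"})
        assert out["label"] == PhenotypeLabel.never_CAD

    def test_no_events_alive_is_no_cad(self):
        out = classify_participant([], PART)
        assert out["label"] == PhenotypeLabel.no_CAD


def test_run_algorithm_on_tiny_cohort(tiny_cohort, codelist):
    assignments, log = run_algorithm(tiny_cohort, codelist)
    got = assignments.set_index("pid")["label"].to_dict()
    assert got == {
        "P1": "prevalent_MI",
        "P2": "incident_CAD_noMI",
        "P3": "sr_MI",
        "P4": "never_CAD",
        "P5": "no_CAD",
    }
    assert log["n"] == 5
    assert log["step5_controls"] == {"never_CAD": 1, "no_CAD": 1}


def test_run_algorithm_empty_cohort(codelist):
    assignments, log = run_algorithm(make_cohort(), codelist)
    assert assignments.empty
    assert log["n"] == 0
    assert log["step1_ehr_mi"] == {"prevalent_MI": 0, "incident_MI": 0}


def test_all_controls_partition(codelist):
    cohort = make_cohort(
        participants=[(f"P{i}", "2008-01-01", "male", 50) for i in range(4)],
        deaths=[("P0", "2012-01-01", "C349", "underlying")],
    )
    assignments, _ = run_algorithm(cohort, codelist)
    agg = aggregate_all_cad(assignments)
    assert agg["never_CAD"] + agg["no_CAD"] == 4
    assert agg["all_CAD"] == 0


def test_idempotent_reruns(small_sim, codelist):
    a1, _ = run_algorithm(small_sim.cohort, codelist)
    a2, _ = run_algorithm(small_sim.cohort, codelist)
    pd.testing.assert_frame_equal(a1, a2)


def test_assignment_date_invariants(small_sim, codelist):
    assignments, _ = run_algorithm(small_sim.cohort, codelist)
    merged = assignments.merge(small_sim.cohort.participants, on="pid")
    undated = merged["label"].isin(["sr_MI", "sr_CAD_noMI", "never_CAD", "no_CAD"])
    assert merged.loc[undated, "qualifying_date"].isna().all()
    assert merged.loc[~undated, "qualifying_date"].notna().all()
    inc = merged["label"].isin(["incident_MI", "incident_CAD_noMI"])
    assert (merged.loc[inc, "qualifying_date"] > merged.loc[inc, "enrol_date"]).all()
    prev = merged["label"].isin(["prevalent_MI", "prevalent_CAD_noMI"])
    assert (merged.loc[prev, "qualifying_date"] <= merged.loc[prev, "enrol_date"]).all()


def test_hierarchy_dominance_under_added_mi_events(codelist):
    """Planting an extra MI diagnosis never moves a participant toward the
    control end of the hierarchy."""
    cohort, _ = simulate_cohort(SimulationConfig(n=400, seed=21, adversarial=True))
    before, _ = run_algorithm(cohort, codelist)
    rng = np.random.default_rng(9)
    touched = rng.choice(cohort.participants["pid"], size=100, replace=False)
    extra = pd.DataFrame(
        {
            "pid": touched,
            "code_system": "ICD10",
            "code": "I219",
            "position": "primary",
            "event_date": pd.Timestamp("2012-05-05"),
        }
    )
    cohort.diagnoses = pd.concat([cohort.diagnoses, extra], ignore_index=True)
    after, _ = run_algorithm(cohort, codelist)
    steps_before = before.set_index("pid")["label"].map(
        lambda l: HIERARCHY_STEP[PhenotypeLabel(l)]
    )
    steps_after = after.set_index("pid")["label"].map(
        lambda l: HIERARCHY_STEP[PhenotypeLabel(l)]
    )
    assert (steps_after <= steps_before).all()


PRINTED_COUNTS = {
    "prevalent_MI": 4_900,
    "incident_MI": 4_621,
    "prevalent_CAD_noMI": 10_910,
    "incident_CAD_noMI": 8_668,
    "sr_MI": 2_754,
    "sr_CAD_noMI": 5_623,
}


def test_aggregate_all_cad_on_count_mapping():
    agg = aggregate_all_cad({**PRINTED_COUNTS, "never_CAD": 0, "no_CAD": 0})
    assert agg["all_CAD"] == 37_476


def test_aggregate_all_cad_zero_counts():
    assert aggregate_all_cad({})["all_CAD"] == 0


def test_summarize_baseline_recovers_planted_male_fractions(codelist):
    cohort, _ = simulate_cohort(SimulationConfig(n=60_000, seed=31))
    assignments, _ = run_algorithm(cohort, codelist)
    table = summarize_baseline(assignments, cohort).set_index("group")
    for group, planted in (("all_CAD", 0.701), ("sr_CAD_noMI", 0.467)):
        n = table.loc[group, "n"]
        frac = table.loc[group, "sex_male_frac"]
        half_ci = 1.96 * np.sqrt(planted * (1 - planted) / n)
        assert abs(frac - planted) < half_ci + 1e-9, group


def test_summarize_baseline_degenerate_groups(codelist):
    cohort = make_cohort(participants=[("P1", "2007-01-01", "male", 55)])
    assignments, _ = run_algorithm(cohort, codelist)
    table = summarize_baseline(assignments, cohort).set_index("group")
    row = table.loc["no_CAD"]
    assert row["n"] == 1
    assert row["age_at_enrol_mean"] == 55
    assert np.isnan(row["age_at_enrol_sd"])  # single member: SD absent
    assert table.loc["prevalent_MI", "n"] == 0
    assert np.isnan(table.loc["prevalent_MI", "age_at_enrol_mean"])
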