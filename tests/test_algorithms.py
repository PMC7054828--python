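"""The 32 built-in variants and the classification rules."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oacphen import (
    AlgorithmSpec,
    SimulationConfig,
    build_cohort,
    builtin_algorithms,
    classify_cohort,
    classify_patient,
    generate_population,
)
from oacphen.algorithms import PredictedLabel, get_algorithm
from oacphen.cohort import apply_vte_exclusion
from oacphen.errors import ConfigurationError

from conftest import make_tables


def test_builtin_family_structure():
    specs = builtin_algorithms()
    assert [s.algo_id for s in specs] == list(range(1, 33))
    windows = [(s.window_start_day, s.window_end_day) for s in specs[:11]]
    assert windows == [(0, 0), (0, 3), (1, 3), (0, 4), (1, 4), (0, 7), (1, 7),
                       (0, 14), (1, 14), (0, 30), (1, 30)]
    assert all(s.appointment_gate == "none" for s in specs[:11])
    s2 = specs[1]
    assert (s2.window_start_day, s2.window_end_day) == (0, 3)
    assert not s2.vte_exclusion
    assert specs[11].appointment_gate == "any_relevant"
    assert (specs[11].window_start_day, specs[11].window_end_day) == (0, 14)
    assert specs[13].include_nephrologist and specs[13].appointment_gate == "any_relevant"
    s15 = specs[14]
    assert s15.require_no_appt_30d_prior and s15.appointment_gate == "any_relevant"
    assert (s15.window_start_day, s15.window_end_day) == (0, 30)
    assert specs[15].appointment_gate == "own_relevant"
    # 17-32 repeat 1-16 with the VTE exclusion
    for base, vte in zip(specs[:16], specs[16:]):
        assert vte.algo_id == base.algo_id + 16
        assert vte.vte_exclusion and not base.vte_exclusion
        for field in ("window_start_day", "window_end_day", "appointment_gate",
                      "include_nephrologist", "require_no_appt_30d_prior"):
            assert getattr(vte, field) == getattr(base, field)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(algo_id=0, window_start_day=5, window_end_day=3),
        dict(algo_id=5, window_start_day=0, window_end_day=3, vte_exclusion=True),
        dict(algo_id=20, window_start_day=0, window_end_day=3, vte_exclusion=False),
        dict(algo_id=0, window_start_day=0, window_end_day=3,
             appointment_gate="sometimes"),
    ],
)
def test_invalid_spec_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        AlgorithmSpec(**kwargs)


def test_predicted_label_invariant():
    with pytest.raises(ValueError):
        PredictedLabel("a", True, None)
    with pytest.raises(ValueError):
        PredictedLabel("a", False, 3)


def _single_patient(fills=(), visits=(), prior_visit=False):
    row = {"patient_id": "a", "index_departure_date": 100,
           "had_relevant_visit_30d_prior": prior_visit,
           "assigned_family_physician_id": "FP1"}
    claims = pd.DataFrame(
        [dict(patient_id="a", fill_date=100 + lag, drug_class="warfarin",
              days_supply=7, prescriber_id="x") for lag in fills],
        columns=["patient_id", "fill_date", "drug_class", "days_supply",
                 "prescriber_id"],
    )
    vis = pd.DataFrame(
        [dict(patient_id="a", service_date=100 + lag, clinician_id=cid,
              specialty=spec) for lag, cid, spec in visits],
        columns=["patient_id", "service_date", "clinician_id", "specialty"],
    )
    return row, claims, vis


def test_day0_fill_included_only_when_window_starts_at_zero():
    row, claims, vis = _single_patient(fills=[0])
    assert classify_patient(row, claims, vis, get_algorithm(2)).positive
    assert not classify_patient(row, claims, vis, get_algorithm(3)).positive


def test_no_fills_is_negative_under_all_32():
    row, claims, vis = _single_patient()
    for spec in builtin_algorithms():
        if spec.vte_exclusion:
            continue  # exclusion applies at cohort level
        assert not classify_patient(row, claims, vis, spec).positive


def test_gate_disqualifies_fill_after_relevant_visit():
    row, claims, vis = _single_patient(
        fills=[5], visits=[(2, "SP1", "family_medicine")]
    )
    assert classify_patient(row, claims, vis, get_algorithm(10)).positive
    assert not classify_patient(row, claims, vis, get_algorithm(13)).positive


def test_same_day_fill_and_visit_is_gated():
    row, claims, vis = _single_patient(fills=[5], visits=[(5, "SP1", "cardiology")])
    assert not classify_patient(row, claims, vis, get_algorithm(13)).positive


def test_gate_ignores_pre_index_visits():
    row, claims, vis = _single_patient(
        fills=[5], visits=[(-10, "SP1", "cardiology")]
    )
    assert classify_patient(row, claims, vis, get_algorithm(13)).positive


def test_nephrologist_visit_gates_only_when_included():
    row, claims, vis = _single_patient(fills=[5], visits=[(2, "SP1", "nephrology")])
    assert classify_patient(row, claims, vis, get_algorithm(13)).positive
    assert not classify_patient(row, claims, vis, get_algorithm(14)).positive


def test_own_clinician_gate_checks_family_physician_identity():
    fills, other_fp, own_fp = [5], (2, "FP9", "family_medicine"), (2, "FP1", "family_medicine")
    row, claims, vis = _single_patient(fills=fills, visits=[other_fp])
    assert classify_patient(row, claims, vis, get_algorithm(16)).positive
    row, claims, vis = _single_patient(fills=fills, visits=[own_fp])
    assert not classify_patient(row, claims, vis, get_algorithm(16)).positive
    # a specialist counts regardless of ownership
    row, claims, vis = _single_patient(fills=fills, visits=[(2, "SP7", "cardiology")])
    assert not classify_patient(row, claims, vis, get_algorithm(16)).positive


def test_prior_appointment_rule_forces_negative_without_shrinking_cohort():
    row, claims, vis = _single_patient(fills=[0], prior_visit=True)
    assert classify_patient(row, claims, vis, get_algorithm(13)).positive
    label = classify_patient(row, claims, vis, get_algorithm(15))
    assert not label.positive


def test_earliest_qualifying_fill_reported():
    row, claims, vis = _single_patient(fills=[7, 2, 20])
    label = classify_patient(row, claims, vis, get_algorithm(10))
    assert label.qualifying_fill_date == 102


def test_vectorized_classifier_matches_per_patient_trace():
    """classify_cohort and the plain rule trace must agree patient by
    patient, for a gated and an ungated variant."""
    t = generate_population(SimulationConfig(n_patients=300, seed=21))
    cohort = build_cohort(t)
    cohort_fp = cohort.merge(
        t.patients[["patient_id", "assigned_family_physician_id"]], on="patient_id"
    )
    claims_by = dict(tuple(t.drug_claims.groupby("patient_id")))
    visits_by = dict(tuple(t.outpatient_visits.groupby("patient_id")))
    empty_claims = t.drug_claims.iloc[0:0]
    empty_visits = t.outpatient_visits.iloc[0:0]
    for algo_id in (1, 2, 10, 13, 15, 16):
        spec = get_algorithm(algo_id)
        fast = classify_cohort(cohort, t, spec).set_index("patient_id")
        for _, row in cohort_fp.iterrows():
            slow = classify_patient(
                row,
                claims_by.get(row["patient_id"], empty_claims),
                visits_by.get(row["patient_id"], empty_visits),
                spec,
            )
            assert bool(fast.loc[row["patient_id"], "positive"]) == slow.positive
            if slow.positive:
                assert fast.loc[row["patient_id"], "qualifying_fill_date"] == \
                    slow.qualifying_fill_date


def _positives(cohort, tables, algo_id):
    pred = classify_cohort(cohort, tables, get_algorithm(algo_id))
    return set(pred.loc[pred["positive"], "patient_id"])


@settings(deadline=None, max_examples=8, derandomize=True)
@given(st.integers(0, 10_000))
def test_window_and_gate_monotonicity(seed):
    """Widening the window never loses a positive; adding a gate or the
    prior-appointment rule never adds one; dropping day 0 never adds one."""
    t = generate_population(SimulationConfig(n_patients=600, seed=seed))
    cohort = build_cohort(t)
    pos = {i: _positives(cohort, t, i) for i in (1, 2, 3, 10, 13, 15)}
    assert pos[1] <= pos[2] <= pos[10]  # window widening is nested
    assert pos[3] <= pos[2]  # dropping day 0 never adds
    assert pos[13] <= pos[10]  # appointment gate never adds
    assert pos[15] <= pos[13]  # prior-appointment rule never adds


def test_conservation_of_labels(tables_small, cohort_small):
    for algo_id in (2, 18):
        spec = get_algorithm(algo_id)
        pred = classify_cohort(cohort_small, tables_small, spec)
        expected = (
            apply_vte_exclusion(cohort_small) if spec.vte_exclusion else cohort_small
        )
        assert len(pred) == len(expected)


def test_empty_cohort_empty_labels(tables_small):
    empty = build_cohort(make_tables())
    assert classify_cohort(empty, tables_small, get_algorithm(2)).empty
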