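"""Cohort construction: study inclusion/exclusion criteria.

One row per eligible patient, anchored at the index (first qualifying) ED
visit. Eligibility: primary atrial-fibrillation diagnosis, discharged
disposition, age at least ``min_age_years`` (completed years at
registration), no oral-anticoagulant claim in the washout window
``[index - washout_days, index - 1]``, and not flagged "would not benefit".
A day-0 fill is a candidate detection event, never prior use, so the washout
window excludes day 0 itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from oacphen.config import CohortCriteria
from oacphen.dates import DAYS_5Y, iso_to_day
from oacphen.errors import LinkageError
from oacphen.simulate import RELEVANT_SPECIALTIES, LinkedTables

COHORT_COLUMNS = [
    "patient_id",
    "index_departure_date",
    "reference_label",
    "vte_within_5y",
    "had_relevant_visit_30d_prior",
]

OAC_CLASSES = ("warfarin", "doac")


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(columns=COHORT_COLUMNS)


def build_cohort(
    tables: LinkedTables, criteria: CohortCriteria | None = None
) -> pd.DataFrame:
    """Apply the study criteria and return one row per eligible patient.

    The index visit is the first qualifying ED visit (earliest registration
    date, ties broken by lowest visit id). ``vte_within_5y`` looks back 1826
    days from the index departure; ``had_relevant_visit_30d_prior`` covers
    outpatient visits with a family physician, cardiologist or internist in
    ``[index - 30, index - 1]``.
    """
    criteria = criteria or CohortCriteria()
    ed = tables.ed_visits
    if ed.empty:
        return _empty_cohort()

    roster = tables.patients.set_index("patient_id")
    unknown = set(ed["patient_id"]) - set(roster.index)
    if unknown:
        raise LinkageError(
            f"{len(unknown)} ED patients absent from roster, e.g. {sorted(unknown)[:3]}"
        )

    ed = ed.merge(
        tables.patients[["patient_id", "birth_date", "would_not_benefit"]],
        on="patient_id",
    )

    keep = np.ones(len(ed), dtype=bool)
    if criteria.require_af_primary:
        keep &= ed["main_diagnosis_is_af"].to_numpy(dtype=bool)
    if criteria.require_discharged:
        keep &= (ed["disposition"] == "discharged").to_numpy()
    age = np.floor(
        (ed["registration_date"] - ed["birth_date"]).to_numpy() / 365.25
    ).astype(int)
    keep &= age >= criteria.min_age_years
    if criteria.study_window_start is not None:
        keep &= ed["registration_date"].to_numpy() >= iso_to_day(criteria.study_window_start)
    if criteria.study_window_end is not None:
        keep &= ed["registration_date"].to_numpy() <= iso_to_day(criteria.study_window_end)
    ed = ed[keep]
    if ed.empty:
        return _empty_cohort()

    # first qualifying visit per patient; tie on date -> lowest visit_id
    ed = ed.sort_values(["patient_id", "registration_date", "visit_id"])
    idx = ed.drop_duplicates("patient_id", keep="first").copy()

    # patient-level exclusions relative to the index visit
    idx = idx[~idx["would_not_benefit"].astype(bool)]

    oac = tables.drug_claims[tables.drug_claims["drug_class"].isin(OAC_CLASSES)]
    if criteria.washout_days > 0 and not oac.empty:
        m = idx[["patient_id", "departure_date"]].merge(
            oac[["patient_id", "fill_date"]], on="patient_id"
        )
        lag = m["fill_date"] - m["departure_date"]
        prior_users = set(
            m.loc[(lag >= -criteria.washout_days) & (lag <= -1), "patient_id"]
        )
        idx = idx[~idx["patient_id"].isin(prior_users)]
    if idx.empty:
        return _empty_cohort()

    # flags used by the VTE sensitivity analysis and the no-prior-appointment
    # algorithm variants
    vte = roster.loc[idx["patient_id"], "vte_dates"]
    dep = idx["departure_date"].to_numpy()
    vte_flag = np.array(
        [
            any(d - DAYS_5Y <= v <= d for v in dates)
            for d, dates in zip(dep, vte)
        ]
    )

    visits = tables.outpatient_visits
    rel = visits[visits["specialty"].isin(RELEVANT_SPECIALTIES)]
    prior_visit = np.zeros(len(idx), dtype=bool)
    if not rel.empty:
        m = idx[["patient_id", "departure_date"]].merge(
            rel[["patient_id", "service_date"]], on="patient_id"
        )
        lag = m["service_date"] - m["departure_date"]
        with_prior = set(m.loc[(lag >= -30) & (lag <= -1), "patient_id"])
        prior_visit = idx["patient_id"].isin(with_prior).to_numpy()

    labels = tables.ground_truth.set_index("patient_id")["ed_oac_prescribed"]
    missing = set(idx["patient_id"]) - set(labels.index)
    if missing:
        raise LinkageError(f"{len(missing)} cohort patients lack a reference label")

    return pd.DataFrame(
        {
            "patient_id": idx["patient_id"].to_numpy(),
            "index_departure_date": dep,
            "reference_label": labels.loc[idx["patient_id"]].to_numpy(dtype=bool),
            "vte_within_5y": vte_flag,
            "had_relevant_visit_30d_prior": prior_visit,
        }
    ).reset_index(drop=True)


def apply_vte_exclusion(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop patients with a VTE diagnosis in the previous 5 years.

    Idempotent; rows without the flag are returned unchanged.
    """
    if cohort.empty:
        return cohort.copy()
    return cohort[~cohort["vte_within_5y"].astype(bool)].reset_index(drop=True)
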