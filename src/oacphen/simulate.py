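"""Synthetic linked administrative tables with known ground truth.

The generator emulates an Ontario-style linkage of four tables — ED visit
records, outpatient drug claims, outpatient physician-visit claims and a
patient roster — plus a chart-review reference-standard label per patient
(whether an oral anticoagulant prescription was actually provided at the
index ED visit).

Every mechanism the fill-window algorithm variants must cope with is
generated explicitly:

* ground-truth positives fill their prescription at an integer day lag drawn
  from ``fill_lag_pmf`` relative to ED departure, unless suppressed by
  primary nonadherence (``p_never_fill``);
* a referring clinician may have written a prescription filled on day 0 by a
  patient the ED did *not* prescribe to (``p_day0_referrer_fill``);
* a post-ED outpatient clinician may prescribe, with the fill on or after
  that clinician's visit (``p_outpatient_prescription``);
* background outpatient visits with relevant clinicians occur on both sides
  of the index visit; prior OAC use, VTE history, admission, age under 65
  and the "would not benefit" flag feed the cohort exclusions.

Dates are integer day offsets from a fixed epoch (see :mod:`oacphen.dates`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from oacphen.config import SimulationConfig, validate_simulation_config

PATIENT_COLUMNS = [
    "patient_id",
    "birth_date",
    "assigned_family_physician_id",
    "vte_dates",
    "would_not_benefit",
]
ED_COLUMNS = [
    "patient_id",
    "visit_id",
    "registration_date",
    "departure_date",
    "main_diagnosis_is_af",
    "disposition",
]
CLAIM_COLUMNS = ["patient_id", "fill_date", "drug_class", "days_supply", "prescriber_id"]
VISIT_COLUMNS = ["patient_id", "service_date", "clinician_id", "specialty"]
TRUTH_COLUMNS = ["patient_id", "ed_oac_prescribed"]

#: specialties whose outpatient visit could explain a subsequent fill
RELEVANT_SPECIALTIES = ("family_medicine", "cardiology", "internal_medicine")

_SPECIALTY_WEIGHTS = {
    "family_medicine": 0.60,
    "cardiology": 0.25,
    "internal_medicine": 0.15,
}


@dataclasses.dataclass
class LinkedTables:
    """The four synthetic administrative tables plus the reference labels."""

    patients: pd.DataFrame
    ed_visits: pd.DataFrame
    drug_claims: pd.DataFrame
    outpatient_visits: pd.DataFrame
    ground_truth: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkedTables):
            return NotImplemented
        return all(
            getattr(self, f.name).reset_index(drop=True).equals(
                getattr(other, f.name).reset_index(drop=True)
            )
            for f in dataclasses.fields(self)
        )


def _empty_tables() -> LinkedTables:
    return LinkedTables(
        patients=pd.DataFrame(columns=PATIENT_COLUMNS),
        ed_visits=pd.DataFrame(columns=ED_COLUMNS),
        drug_claims=pd.DataFrame(columns=CLAIM_COLUMNS),
        outpatient_visits=pd.DataFrame(columns=VISIT_COLUMNS),
        ground_truth=pd.DataFrame(columns=TRUTH_COLUMNS),
    )


def generate_population(config: SimulationConfig | dict) -> LinkedTables:
    """Generate a seeded population; a pure function of the config.

    Returns the five record collections sorted in a stable order so that the
    serialized form is byte-identical across calls with the same config.
    """
    cfg = validate_simulation_config(config)
    n = cfg.n_patients
    if n == 0:
        return _empty_tables()
    rng = np.random.default_rng(cfg.seed)

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- index ED visit ----------------------------------------------------
    departure = rng.integers(0, cfg.study_window_days + 1, n)
    # a minority of visits span midnight: registration the day before
    registration = departure - (rng.random(n) < 0.3).astype(int)
    admitted = rng.random(n) < cfg.p_admitted

    # --- roster ------------------------------------------------------------
    under65 = rng.random(n) < cfg.p_under65
    age_exact = np.where(
        under65, rng.uniform(40.0, 64.9, n), rng.uniform(65.1, 94.9, n)
    )
    birth = registration - np.round(age_exact * 365.25).astype(int)
    n_fp = max(1, n // 10)
    fp_ids = np.array([f"FP{i:05d}" for i in range(n_fp)])
    assigned_fp = fp_ids[rng.integers(0, n_fp, n)]
    would_not_benefit = rng.random(n) < cfg.p_would_not_benefit

    has_vte = rng.random(n) < cfg.p_vte_history
    vte_offsets = rng.integers(30, 1800, n)
    vte_dates = [
        (int(departure[i] - vte_offsets[i]),) if has_vte[i] else ()
        for i in range(n)
    ]

    # --- ground truth and ED-prescription fills ----------------------------
    gt_positive = rng.random(n) < cfg.p_ed_prescription
    never_fill = rng.random(n) < cfg.p_never_fill
    lag = rng.choice(len(cfg.fill_lag_pmf), size=n, p=np.asarray(cfg.fill_lag_pmf))
    warfarin = rng.random(n) < cfg.p_warfarin
    n_ed_md = 40
    ed_md = np.array([f"EDMD{i:03d}" for i in range(n_ed_md)])[rng.integers(0, n_ed_md, n)]

    claims: list[pd.DataFrame] = []

    def _claims_frame(mask, fill_day, prescriber):
        drug = np.where(warfarin[mask], "warfarin", "doac")
        supply = np.where(
            warfarin[mask], cfg.warfarin_days_supply, cfg.doac_days_supply
        )
        return pd.DataFrame(
            {
                "patient_id": patient_ids[mask],
                "fill_date": fill_day,
                "drug_class": drug,
                "days_supply": supply.astype(int),
                "prescriber_id": prescriber,
            }
        )

    ed_filled = gt_positive & ~never_fill
    claims.append(
        _claims_frame(ed_filled, (departure + lag)[ed_filled], ed_md[ed_filled])
    )

    # day-0 fill written by the clinician who sent the patient in
    day0_ref = ~gt_positive & (rng.random(n) < cfg.p_day0_referrer_fill)
    claims.append(_claims_frame(day0_ref, departure[day0_ref], assigned_fp[day0_ref]))

    # outpatient-origin prescription: clinician visit at day v >= 1, fill on
    # or after that visit — the false-positive mechanism the appointment-gate
    # variants are built to remove
    out_rx = ~gt_positive & (rng.random(n) < cfg.p_outpatient_prescription)
    out_visit_lag = rng.integers(1, 31, n)
    out_fill_delay = rng.integers(0, 4, n)
    out_spec = rng.choice(
        list(_SPECIALTY_WEIGHTS), size=n, p=list(_SPECIALTY_WEIGHTS.values())
    )
    n_sp = max(1, n // 20)
    sp_ids = np.array([f"SP{i:04d}" for i in range(n_sp)])
    out_clin = np.where(
        out_spec == "family_medicine", assigned_fp, sp_ids[rng.integers(0, n_sp, n)]
    )
    claims.append(
        _claims_frame(
            out_rx, (departure + out_visit_lag + out_fill_delay)[out_rx], out_clin[out_rx]
        )
    )

    # prior OAC use inside the washout window
    prior = rng.random(n) < cfg.p_prior_oac
    prior_day = departure - rng.integers(1, 91, n)
    claims.append(_claims_frame(prior, prior_day[prior], assigned_fp[prior]))

    # --- outpatient physician visits ---------------------------------------
    visits: list[pd.DataFrame] = []
    visits.append(
        pd.DataFrame(
            {
                "patient_id": patient_ids[out_rx],
                "service_date": (departure + out_visit_lag)[out_rx],
                "clinician_id": out_clin[out_rx],
                "specialty": out_spec[out_rx],
            }
        )
    )
    # background relevant-clinician visits over days -30..+30
    n_bg = rng.poisson(cfg.outpatient_visit_rate, n)
    total_bg = int(n_bg.sum())
    if total_bg:
        bg_pid = np.repeat(np.arange(n), n_bg)
        bg_day = departure[bg_pid] + rng.integers(-30, 31, total_bg)
        bg_spec = rng.choice(
            list(_SPECIALTY_WEIGHTS), size=total_bg, p=list(_SPECIALTY_WEIGHTS.values())
        )
        own_fp = rng.random(total_bg) < 0.7
        bg_clin = np.where(
            (bg_spec == "family_medicine") & own_fp,
            assigned_fp[bg_pid],
            sp_ids[rng.integers(0, n_sp, total_bg)],
        )
        visits.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[bg_pid],
                    "service_date": bg_day,
                    "clinician_id": bg_clin,
                    "specialty": bg_spec,
                }
            )
        )
    # sprinkle of specialties outside the core relevant set (nephrology is
    # relevant only to the variants that opt in; "other" never is)
    n_other = rng.poisson(0.15 * cfg.outpatient_visit_rate, n)
    total_other = int(n_other.sum())
    if total_other:
        ot_pid = np.repeat(np.arange(n), n_other)
        visits.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[ot_pid],
                    "service_date": departure[ot_pid] + rng.integers(-30, 31, total_other),
                    "clinician_id": sp_ids[rng.integers(0, n_sp, total_other)],
                    "specialty": rng.choice(
                        ["nephrology", "other"], size=total_other, p=[0.4, 0.6]
                    ),
                }
            )
        )

    # --- ED visit table (optional later duplicate visits) ------------------
    ed = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "visit_id": [f"V{i:07d}" for i in range(n)],
            "registration_date": registration,
            "departure_date": departure,
            "main_diagnosis_is_af": True,
            "disposition": np.where(admitted, "admitted", "discharged"),
        }
    )
    dup = rng.random(n) < cfg.p_duplicate_visit
    if dup.any():
        gap = rng.integers(30, 181, n)
        dup_dep = (departure + gap)[dup]
        ed_dup = pd.DataFrame(
            {
                "patient_id": patient_ids[dup],
                "visit_id": [f"V{n + i:07d}" for i in range(int(dup.sum()))],
                "registration_date": dup_dep,
                "departure_date": dup_dep,
                "main_diagnosis_is_af": True,
                "disposition": "discharged",
            }
        )
        ed = pd.concat([ed, ed_dup], ignore_index=True)

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_date": birth,
            "assigned_family_physician_id": assigned_fp,
            "vte_dates": vte_dates,
            "would_not_benefit": would_not_benefit,
        }
    )
    truth = pd.DataFrame({"patient_id": patient_ids, "ed_oac_prescribed": gt_positive})

    drug_claims = pd.concat(claims, ignore_index=True)
    outpatient_visits = pd.concat(visits, ignore_index=True)

    return LinkedTables(
        patients=patients.sort_values("patient_id", ignore_index=True)[PATIENT_COLUMNS],
        ed_visits=ed.sort_values(["patient_id", "visit_id"], ignore_index=True)[ED_COLUMNS],
        drug_claims=drug_claims.sort_values(
            ["patient_id", "fill_date", "drug_class"], ignore_index=True
        )[CLAIM_COLUMNS].astype({"fill_date": int, "days_supply": int}),
        outpatient_visits=outpatient_visits.sort_values(
            ["patient_id", "service_date", "clinician_id"], ignore_index=True
        )[VISIT_COLUMNS].astype({"service_date": int}),
        ground_truth=truth.sort_values("patient_id", ignore_index=True)[TRUTH_COLUMNS],
    )
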