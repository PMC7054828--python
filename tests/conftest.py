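import pandas as pd
import pytest

from oacphen import LinkedTables, SimulationConfig, build_cohort, generate_population
from oacphen.simulate import (
    CLAIM_COLUMNS,
    ED_COLUMNS,
    PATIENT_COLUMNS,
    TRUTH_COLUMNS,
    VISIT_COLUMNS,
)


def noise_free_config(**overrides) -> SimulationConfig:
    """All false-positive/false-negative mechanisms switched off."""
    base = dict(
        n_patients=1000,
        p_ed_prescription=0.5,
        fill_lag_pmf=(1.0,),
        p_never_fill=0.0,
        p_day0_referrer_fill=0.0,
        p_outpatient_prescription=0.0,
        outpatient_visit_rate=0.0,
        p_vte_history=0.0,
        p_prior_oac=0.0,
        p_admitted=0.0,
        p_under65=0.0,
        p_would_not_benefit=0.0,
        seed=42,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def make_tables(patients=(), ed_visits=(), drug_claims=(), outpatient_visits=(),
                ground_truth=()) -> LinkedTables:
    """Hand-build linked tables from row dicts, filling schema defaults."""
    defaults = {
        "patients": dict(birth_date=-30000, assigned_family_physician_id="FP00000",
                         vte_dates=(), would_not_benefit=False),
        "ed_visits": dict(visit_id="V0000001", registration_date=100,
                          departure_date=100, main_diagnosis_is_af=True,
                          disposition="discharged"),
        "drug_claims": dict(fill_date=100, drug_class="warfarin", days_supply=7,
                            prescriber_id="EDMD000"),
        "outpatient_visits": dict(service_date=100, clinician_id="SP0000",
                                  specialty="family_medicine"),
        "ground_truth": dict(ed_oac_prescribed=False),
    }
    columns = {
        "patients": PATIENT_COLUMNS,
        "ed_visits": ED_COLUMNS,
        "drug_claims": CLAIM_COLUMNS,
        "outpatient_visits": VISIT_COLUMNS,
        "ground_truth": TRUTH_COLUMNS,
    }
    frames = {}
    for name, rows in [("patients", patients), ("ed_visits", ed_visits),
                       ("drug_claims", drug_claims),
                       ("outpatient_visits", outpatient_visits),
                       ("ground_truth", ground_truth)]:
        full = [{**defaults[name], **row} for row in rows]
        frames[name] = pd.DataFrame(full, columns=columns[name])
    return LinkedTables(**frames)


@pytest.fixture(scope="session")
def tables_small():
    return generate_population(SimulationConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def cohort_small(tables_small):
    return build_cohort(tables_small)
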