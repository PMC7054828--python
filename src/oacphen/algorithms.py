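"""The fill-window algorithm family and patient classification.

An algorithm calls a cohort patient positive when an oral-anticoagulant
claim is filled within a day window relative to ED departure (day 0 = the
day the patient left the ED), optionally gated on the fill occurring before
any post-ED outpatient visit with a relevant clinician (family physician,
cardiologist, internist; optionally nephrologist), and optionally forcing
negative any patient who saw a relevant clinician in the 30 days before the
ED visit. Sixteen such variants, each with and without excluding patients
with a 5-year VTE history, give the 32 built-in algorithms.

Conventions (day arithmetic is inclusive on both window ends):

* a fill on the same calendar day as a relevant outpatient visit is treated
  as occurring *after* the visit, so the gate disqualifies it;
* the gate considers only visits on or after day 0 — pre-index visits act
  solely through the 30-days-prior rule;
* "their own" clinician restricts family-medicine visits to the patient's
  rostered family physician; cardiology/internal-medicine visits count
  regardless, since the roster assigns only a family physician;
* any single qualifying fill suffices; the earliest is reported.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Optional

import pandas as pd

from oacphen.cohort import OAC_CLASSES, apply_vte_exclusion
from oacphen.errors import ConfigurationError
from oacphen.simulate import LinkedTables

Gate = Literal["none", "any_relevant", "own_relevant"]

_CORE_SPECIALTIES = ("family_medicine", "cardiology", "internal_medicine")


@dataclasses.dataclass(frozen=True)
class AlgorithmSpec:
    """Parameter tuple defining one fill-window algorithm.

    ``algo_id`` 1..32 are the built-in variants (17..32 repeat 1..16 with
    the VTE exclusion); 0 marks a custom spec.
    """

    algo_id: int
    window_start_day: int
    window_end_day: int
    appointment_gate: Gate = "none"
    include_nephrologist: bool = False
    require_no_appt_30d_prior: bool = False
    vte_exclusion: bool = False

    def __post_init__(self) -> None:
        if self.window_start_day < 0 or self.window_start_day > self.window_end_day:
            raise ConfigurationError(
                f"invalid window {self.window_start_day}-{self.window_end_day}"
            )
        if self.appointment_gate not in ("none", "any_relevant", "own_relevant"):
            raise ConfigurationError(f"unknown gate {self.appointment_gate!r}")
        if not 0 <= self.algo_id <= 32:
            raise ConfigurationError(f"algo_id {self.algo_id} outside 0..32")
        if 1 <= self.algo_id <= 16 and self.vte_exclusion:
            raise ConfigurationError("algorithms 1-16 do not use the VTE exclusion")
        if 17 <= self.algo_id <= 32 and not self.vte_exclusion:
            raise ConfigurationError("algorithms 17-32 require the VTE exclusion")

    @property
    def window_label(self) -> str:
        if self.window_start_day == self.window_end_day:
            return str(self.window_start_day)
        return f"{self.window_start_day}-{self.window_end_day}"

    def relevant_specialties(self) -> tuple[str, ...]:
        if self.include_nephrologist:
            return _CORE_SPECIALTIES + ("nephrology",)
        return _CORE_SPECIALTIES


@dataclasses.dataclass(frozen=True)
class PredictedLabel:
    patient_id: str
    positive: bool
    qualifying_fill_date: Optional[int] = None

    def __post_init__(self) -> None:
        if self.positive != (self.qualifying_fill_date is not None):
            raise ValueError("positive iff qualifying_fill_date present")


_BASE_16: list[dict] = [
    dict(window=(0, 0)),
    dict(window=(0, 3)),
    dict(window=(1, 3)),
    dict(window=(0, 4)),
    dict(window=(1, 4)),
    dict(window=(0, 7)),
    dict(window=(1, 7)),
    dict(window=(0, 14)),
    dict(window=(1, 14)),
    dict(window=(0, 30)),
    dict(window=(1, 30)),
    dict(window=(0, 14), gate="any_relevant"),
    dict(window=(0, 30), gate="any_relevant"),
    dict(window=(0, 30), gate="any_relevant", nephrologist=True),
    dict(window=(0, 30), gate="any_relevant", no_prior=True),
    dict(window=(0, 30), gate="own_relevant"),
]


def builtin_algorithms() -> list[AlgorithmSpec]:
    """The 32 built-in variants, in publication order."""
    specs = []
    for vte in (False, True):
        for i, d in enumerate(_BASE_16):
            specs.append(
                AlgorithmSpec(
                    algo_id=i + 1 + (16 if vte else 0),
                    window_start_day=d["window"][0],
                    window_end_day=d["window"][1],
                    appointment_gate=d.get("gate", "none"),
                    include_nephrologist=d.get("nephrologist", False),
                    require_no_appt_30d_prior=d.get("no_prior", False),
                    vte_exclusion=vte,
                )
            )
    return specs


def get_algorithm(algo_id: int) -> AlgorithmSpec:
    if not 1 <= algo_id <= 32:
        raise ConfigurationError(f"no built-in algorithm {algo_id}")
    return builtin_algorithms()[algo_id - 1]


def classify_patient(
    row, claims: pd.DataFrame, visits: pd.DataFrame, spec: AlgorithmSpec
) -> PredictedLabel:
    """Classify one cohort row by a direct trace of the rules.

    ``row`` is a cohort row (mapping with ``patient_id``,
    ``index_departure_date``, ``had_relevant_visit_30d_prior``); ``claims``
    and ``visits`` hold that patient's drug claims and outpatient visits.
    Kept deliberately plain — the vectorized :func:`classify_cohort` must
    agree with it patient by patient.
    """
    pid = row["patient_id"]
    day0 = int(row["index_departure_date"])

    if spec.require_no_appt_30d_prior and bool(row["had_relevant_visit_30d_prior"]):
        return PredictedLabel(pid, False)

    gate_date = None
    if spec.appointment_gate != "none":
        rel = visits[visits["specialty"].isin(spec.relevant_specialties())]
        if spec.appointment_gate == "own_relevant":
            own = rel["clinician_id"] == row.get("assigned_family_physician_id")
            rel = rel[(rel["specialty"] != "family_medicine") | own]
        rel = rel[rel["service_date"] >= day0]
        if len(rel):
            gate_date = int(rel["service_date"].min())

    fills = claims[claims["drug_class"].isin(OAC_CLASSES)]["fill_date"]
    qualifying = sorted(
        int(f)
        for f in fills
        if spec.window_start_day <= f - day0 <= spec.window_end_day
        and (gate_date is None or f < gate_date)
    )
    if qualifying:
        return PredictedLabel(pid, True, qualifying[0])
    return PredictedLabel(pid, False)


def classify_cohort(
    cohort: pd.DataFrame, tables: LinkedTables, spec: AlgorithmSpec
) -> pd.DataFrame:
    """Classify every (post-exclusion) cohort patient under one algorithm.

    Applies the VTE exclusion internally when the spec asks for it. Returns
    a frame with ``patient_id``, ``positive`` and ``qualifying_fill_date``
    (NA when negative), one row per classified patient.
    """
    if spec.vte_exclusion:
        cohort = apply_vte_exclusion(cohort)
    if cohort.empty:
        return pd.DataFrame(columns=["patient_id", "positive", "qualifying_fill_date"])

    base = cohort[["patient_id", "index_departure_date"]].copy()

    oac = tables.drug_claims[tables.drug_claims["drug_class"].isin(OAC_CLASSES)]
    m = base.merge(oac[["patient_id", "fill_date"]], on="patient_id", how="inner")
    lag = m["fill_date"] - m["index_departure_date"]
    m = m[(lag >= spec.window_start_day) & (lag <= spec.window_end_day)]

    if spec.appointment_gate != "none" and not m.empty:
        visits = tables.outpatient_visits
        rel = visits[visits["specialty"].isin(spec.relevant_specialties())]
        if spec.appointment_gate == "own_relevant":
            rel = rel.merge(
                tables.patients[["patient_id", "assigned_family_physician_id"]],
                on="patient_id",
            )
            rel = rel[
                (rel["specialty"] != "family_medicine")
                | (rel["clinician_id"] == rel["assigned_family_physician_id"])
            ]
        rv = base.merge(rel[["patient_id", "service_date"]], on="patient_id")
        rv = rv[rv["service_date"] >= rv["index_departure_date"]]
        first_visit = rv.groupby("patient_id")["service_date"].min()
        gate = m["patient_id"].map(first_visit)
        m = m[gate.isna() | (m["fill_date"] < gate)]

    earliest = m.groupby("patient_id")["fill_date"].min()
    out = cohort[["patient_id"]].copy()
    out["qualifying_fill_date"] = out["patient_id"].map(earliest).astype("Int64")
    if spec.require_no_appt_30d_prior:
        blocked = cohort["had_relevant_visit_30d_prior"].to_numpy(dtype=bool)
        out.loc[blocked, "qualifying_fill_date"] = pd.NA
    out["positive"] = out["qualifying_fill_date"].notna()
    return out[["patient_id", "positive", "qualifying_fill_date"]].reset_index(drop=True)


def classify_all(
    cohort: pd.DataFrame,
    tables: LinkedTables,
    specs: Iterable[AlgorithmSpec],
) -> dict[int, pd.DataFrame]:
    """Convenience: classify under several algorithms at once."""
    return {spec.algo_id: classify_cohort(cohort, tables, spec) for spec in specs}
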