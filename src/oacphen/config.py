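"""Configuration models for the simulator, cohort criteria and pipeline runs.

Configs are pydantic models so that a YAML file mirroring the field names
validates on load; invalid probabilities or an unnormalized fill-lag pmf
raise :class:`~oacphen.errors.ConfigurationError`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pydantic
import yaml

from oacphen.errors import ConfigurationError

_PMF_TOL = 1e-9


class _Model(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True)


Prob = pydantic.confloat(ge=0.0, le=1.0)


class SimulationConfig(_Model):
    """Parameters of the synthetic linked-claims generator.

    Each probability switches on one mechanism the fill-window algorithm
    variants are designed to handle: day-0 fills written by a referring
    clinician and outpatient-origin prescriptions create false positives;
    primary nonadherence (a prescription never filled) creates false
    negatives; prior OAC use, admission, age under 65 and the
    "would not benefit" flag feed the cohort exclusions.
    """

    n_patients: int = pydantic.Field(default=2000, ge=0)
    p_ed_prescription: Prob = 0.20
    fill_lag_pmf: Sequence[float] = (0.45, 0.25, 0.12, 0.08, 0.04, 0.03, 0.02, 0.01)
    p_never_fill: Prob = 0.15
    p_day0_referrer_fill: Prob = 0.02
    p_outpatient_prescription: Prob = 0.20
    outpatient_visit_rate: float = pydantic.Field(default=2.0, ge=0.0)
    p_vte_history: Prob = 0.03
    p_prior_oac: Prob = 0.25
    p_admitted: Prob = 0.30
    p_under65: Prob = 0.30
    p_would_not_benefit: Prob = 0.02
    seed: int = 0

    # secondary knobs; defaults echo the descriptive medians for days supplied
    p_warfarin: Prob = 0.5
    warfarin_days_supply: int = pydantic.Field(default=7, ge=1)
    doac_days_supply: int = pydantic.Field(default=30, ge=1)
    p_duplicate_visit: Prob = 0.0
    study_window_days: int = pydantic.Field(default=1825, ge=0)

    @pydantic.field_validator("fill_lag_pmf")
    @classmethod
    def _check_pmf(cls, v: Sequence[float]) -> tuple[float, ...]:
        v = tuple(float(x) for x in v)
        if not v or len(v) > 31:
            raise ValueError("fill_lag_pmf must cover integer lags 0..30")
        if any(x < 0 for x in v):
            raise ValueError("fill_lag_pmf entries must be non-negative")
        if abs(sum(v) - 1.0) > _PMF_TOL:
            raise ValueError(f"fill_lag_pmf sums to {sum(v)!r}, not 1")
        return v


class CohortCriteria(_Model):
    """Inclusion/exclusion rules applied to the linked tables.

    Defaults encode the study design: age 65 or older at the index visit,
    discharged (not admitted), primary atrial-fibrillation diagnosis, and a
    90-day oral-anticoagulant washout before the index visit.
    """

    min_age_years: int = pydantic.Field(default=65, ge=0)
    washout_days: int = pydantic.Field(default=90, ge=0)
    require_discharged: bool = True
    require_af_primary: bool = True
    study_window_start: Optional[str] = None  # ISO date, inclusive
    study_window_end: Optional[str] = None  # ISO date, inclusive


class RunConfig(_Model):
    """Everything one end-to-end validation run needs."""

    simulation: SimulationConfig = SimulationConfig()
    cohort: CohortCriteria = CohortCriteria()
    algorithm_ids: tuple[int, ...] = tuple(range(1, 33))
    output_directory: Path = Path("oacphen_output")
    log_level: str = "INFO"

    @pydantic.field_validator("algorithm_ids")
    @classmethod
    def _check_ids(cls, v: Sequence[int]) -> tuple[int, ...]:
        v = tuple(int(i) for i in v)
        if not v:
            raise ValueError("algorithm_ids must not be empty")
        bad = [i for i in v if not 1 <= i <= 32]
        if bad:
            raise ValueError(f"algorithm ids out of range 1..32: {bad}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; raise ``ConfigurationError`` on
    unparseable or invalid content."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def validate_simulation_config(raw: dict | SimulationConfig) -> SimulationConfig:
    if isinstance(raw, SimulationConfig):
        return raw
    try:
        return SimulationConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
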