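"""Configuration models for the synthetic cohort generator and the pipeline.

All tunables of the data-generating mechanism live in :class:`SimulationConfig`
so that every study condition (event rates, nurse-response dynamics, covariate
prevalences, the outcome model, charge distributions) is explicit and
serializable.  Validation is handled by pydantic; the invariants mirror the
generator's contract: probabilities in [0, 1], rates non-negative, and a fixed
seed implying byte-identical output.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

PHENOTYPES = ("low", "moderate", "high")


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


class ChargeLogNormal(BaseModel):
    """Log-normal location/scale for one oxygen-duration stratum."""

    mu: float
    sigma: float = Field(gt=0)


class SimulationConfig(BaseModel):
    """Ground-truth data-generating mechanism for a synthetic PACU cohort.

    Defaults describe a large academic-center PACU population: per-minute
    SpO2 around 97% with most values in the normal range, episodic
    desaturation events whose frequency scales with OSA-risk phenotype,
    nurse-driven oxygen therapy triggered by sustained sub-alarm readings,
    a rare binary respiratory-complication outcome (~0.3%), and
    right-skewed hospital charges that rise with oxygen-therapy duration.
    """

    n_patients: int = Field(default=1000, ge=1)
    seed: int = Field(default=0, ge=0)

    pacu_duration_min: int = Field(default=120, ge=1)
    # Optional shorter stays to exercise the missingness pathway: probability
    # that a patient's stay is drawn uniformly from [min_short_stay, 120).
    short_stay_probability: float = Field(default=0.0, ge=0.0, le=1.0)
    min_short_stay_min: int = Field(default=20, ge=1)

    baseline_spo2_mean: float = 97.0
    baseline_spo2_sd: float = Field(default=1.0, ge=0.0)
    # between-patient spread of the resting SpO2 level; gives the cohort a
    # non-degenerate distribution of per-patient medians
    baseline_between_sd: float = Field(default=1.5, ge=0.0)

    # Episodic desaturation: homogeneous Poisson onsets (events/hour) by
    # OSA-risk phenotype, exponential durations, Gaussian depths.
    event_rate_by_phenotype: Dict[str, float] = Field(
        default_factory=lambda: {"low": 0.2, "moderate": 1.0, "high": 3.0}
    )
    event_depth_mean: float = Field(default=8.0, ge=0.0)
    event_depth_sd: float = Field(default=3.0, ge=0.0)
    event_duration_mean: float = Field(default=3.0, gt=0.0)

    # Nurse-intervention dynamics.
    alarm_threshold: float = 90.0
    nurse_response_delay: int = Field(default=2, ge=0)
    o2_uplift: float = Field(default=4.0, ge=0.0)
    o2_washout_min: int = Field(default=10, ge=0)
    manual_roomair_probability: float = Field(default=0.3, ge=0.0, le=1.0)
    # many patients arrive on supplemental oxygen regardless of events;
    # duration uniform on [prophylactic_o2_min, stay] from admission
    prophylactic_o2_probability: float = Field(default=0.85, ge=0.0, le=1.0)
    prophylactic_o2_min: int = Field(default=5, ge=0)

    phenotype_probabilities: Dict[str, float] = Field(
        default_factory=lambda: {"low": 0.48, "moderate": 0.44, "high": 0.08}
    )
    covariate_prevalences: Dict[str, float] = Field(
        default_factory=lambda: {
            "copd": 0.06,
            "renal_disease": 0.09,
            "chf": 0.03,
            "neuro_disease": 0.13,
            "steroid": 0.04,
            "pneumonia": 0.03,
            "sepsis": 0.01,
            "smoking": 0.13,
            "high_risk_surgery": 0.39,
            "asa_4_5": 0.03,
        }
    )
    # Log-odds of the early-PRC outcome.  Terms must be 'intercept',
    # 'phenotype_moderate'/'phenotype_high', or a configured covariate name.
    outcome_coefficients: Dict[str, float] = Field(
        default_factory=lambda: {
            "intercept": logit(0.0015),
            "phenotype_moderate": 0.9,
            "phenotype_high": 1.8,
            "copd": math.log(2.5),
            "renal_disease": math.log(2.0),
            "sepsis": math.log(3.0),
            "asa_4_5": math.log(3.0),
        }
    )

    # Charges by oxygen-duration quartile stratum (minute bins of a 120-min
    # stay: <30, 31-60, 61-90, >90), log-dollars.
    charge_lognormal_params: List[ChargeLogNormal] = Field(
        default_factory=lambda: [
            ChargeLogNormal(mu=9.23, sigma=0.55),
            ChargeLogNormal(mu=9.92, sigma=0.65),
            ChargeLogNormal(mu=10.08, sigma=0.65),
            ChargeLogNormal(mu=10.08, sigma=0.65),
        ]
    )

    # Auxiliary per-patient attributes used by dose normalization and the
    # procedure-complexity pathway.
    procedure_regions: List[str] = Field(
        default_factory=lambda: [
            "head", "neck", "intrathoracic", "upper_abdomen",
            "lower_abdomen", "extremity", "perineum", "spine",
        ]
    )

    @field_validator("event_rate_by_phenotype")
    @classmethod
    def _rates_nonnegative(cls, v: Dict[str, float]) -> Dict[str, float]:
        for k in PHENOTYPES:
            if k not in v:
                raise ValueError(f"event_rate_by_phenotype missing stratum {k!r}")
        if any(r < 0 for r in v.values()):
            raise ValueError("event rates must be >= 0")
        return v

    @field_validator("covariate_prevalences", "phenotype_probabilities")
    @classmethod
    def _probs_in_unit_interval(cls, v: Dict[str, float]) -> Dict[str, float]:
        if any(not (0.0 <= p <= 1.0) for p in v.values()):
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_terms(self) -> "SimulationConfig":
        if abs(sum(self.phenotype_probabilities.get(k, 0.0) for k in PHENOTYPES) - 1.0) > 1e-9:
            raise ValueError("phenotype probabilities must sum to 1")
        if len(self.charge_lognormal_params) != 4:
            raise ValueError("charge_lognormal_params requires one entry per oxygen quartile")
        known = {"intercept", "phenotype_moderate", "phenotype_high"} | set(
            self.covariate_prevalences
        )
        for term in self.outcome_coefficients:
            if term not in known:
                raise ValueError(f"outcome coefficient references unknown term {term!r}")
        if "intercept" not in self.outcome_coefficients:
            raise ValueError("outcome_coefficients must include 'intercept'")
        return self


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (stage toggles + module parameters)."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    censor_minutes: int = 120
    artifact_floor: float = 60.0
    window_min: int = 5
    desaturation_level: Optional[float] = None  # None -> population median cut
    nadir_uses_full_stay: bool = True
    change_in_estimate_threshold: float = 0.10
    interaction_alpha: float = 0.05
    matching_caliper: Optional[float] = None
    procedure_frequency_floor: int = 50
    run_univariate: bool = True
    run_models: bool = True
    run_matching: bool = True
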