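"""Configuration schema, validation, and the shipped default parameter set.

The YAML config is the single source of every model input: economic
settings, utilities, dosing/price structure per arm, adverse-event tables,
the assistance-program tier schedule, the fitted survival parameters for
each analysis scenario, and the sensitivity-analysis distributions. The
shipped default (``data/default_config.yaml``) encodes the published
base-case inputs; ``load_config`` validates any user file against the same
schema, naming the offending field on error.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .costing import (
    AdverseEvent,
    CostInputs,
    PAPSchedule,
    PatientProfile,
    RegimenComponent,
    RegimenSpec,
)
from .engine import EconParams, UtilitySet
from .survival import ParametricSurvival

__all__ = ["ModelConfig", "load_config", "default_config", "dump_config", "config_hash"]


class EconSchema(BaseModel):
    discount_rate: float = Field(0.05, ge=0)
    cycle_days: float = Field(21.0, gt=0)
    horizon_years: float = Field(10.0, gt=0)
    wtp: float = Field(23901.90, gt=0)


class UtilitySchema(BaseModel):
    pfs: float = Field(0.75, ge=0, le=1)
    pd: float = Field(0.60, ge=0, le=1)

    @model_validator(mode="after")
    def _ordered(self):
        if self.pd > self.pfs:
            raise ValueError("utility of PD must not exceed utility of PFS")
        return self


class ProfileSchema(BaseModel):
    weight_kg: float = Field(65.0, gt=0)
    bsa_m2: float = Field(1.72, gt=0)


class ComponentSchema(BaseModel):
    name: str
    dose_mg: float = Field(gt=0)
    basis: Literal["flat", "per_m2"] = "flat"
    administrations_per_cycle: int = Field(1, ge=1)
    vial_mg: float = Field(gt=0)
    vial_price: float = Field(ge=0)
    max_cycles: Optional[int] = Field(None, ge=1)
    pap_eligible: bool = False


class AESchema(BaseModel):
    name: str
    incidence: float = Field(ge=0, le=1)
    unit_cost: float = Field(ge=0)


class CostSchema(BaseModel):
    post_progression_per_cycle: float = Field(753.49, ge=0)
    hospitalization_per_cycle: float = Field(142.10, ge=0)
    adverse_events: dict[str, list[AESchema]]


class SurvivalSchema(BaseModel):
    family: Literal[
        "exponential", "weibull", "loglogistic", "lognormal", "gompertz", "gengamma"
    ]
    params: list[float]


class ScenarioSchema(BaseModel):
    survival: dict[str, dict[Literal["pfs", "os"], SurvivalSchema]]
    pap: bool = False


class DistributionSchema(BaseModel):
    name: str
    base: float
    low: float
    high: float
    family: Literal["gamma", "beta"]
    role: Literal["cost", "utility", "probability", "rate"]

    @model_validator(mode="after")
    def _ordered(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")
        return self


class SimulationSchema(BaseModel):
    n_per_arm: dict[str, int]
    cutoff_cycles: float = Field(35.0, gt=0)
    dropout_rate: float = Field(0.05, ge=0, lt=1)
    seed: int = 20304


class ModelConfig(BaseModel):
    """Validated model configuration; see the shipped default for the layout."""

    econ: EconSchema = EconSchema()
    utilities: UtilitySchema = UtilitySchema()
    profile: ProfileSchema = ProfileSchema()
    arms: list[str]
    control_arm: str
    regimens: dict[str, list[ComponentSchema]]
    costs: CostSchema
    pap_tiers: list[list[int]] = Field(default=[[2, 2], [2, 25], [1, 3]])
    scenarios: dict[str, ScenarioSchema]
    distributions: list[DistributionSchema] = []
    simulation: Optional[SimulationSchema] = None

    @model_validator(mode="after")
    def _arms_consistent(self):
        for arm in self.arms:
            if arm not in self.regimens:
                raise ValueError(f"arm {arm!r} has no regimen")
            if arm not in self.costs.adverse_events:
                raise ValueError(f"arm {arm!r} has no adverse-event table")
        if self.control_arm not in self.arms:
            raise ValueError("control_arm must be one of arms")
        for label, sc in self.scenarios.items():
            for arm in self.arms:
                if arm not in sc.survival:
                    raise ValueError(f"scenario {label!r} missing survival for arm {arm!r}")
        return self

    # ---- typed-object accessors -------------------------------------------------

    def econ_params(self) -> EconParams:
        e = self.econ
        return EconParams(e.discount_rate, e.cycle_days, e.horizon_years, e.wtp)

    def utility_set(self) -> UtilitySet:
        return UtilitySet(self.utilities.pfs, self.utilities.pd)

    def patient_profile(self) -> PatientProfile:
        return PatientProfile(self.profile.weight_kg, self.profile.bsa_m2)

    def regimen(self, arm: str) -> RegimenSpec:
        return RegimenSpec(
            tuple(RegimenComponent(**c.model_dump()) for c in self.regimens[arm])
        )

    def cost_inputs(self, arm: str) -> CostInputs:
        return CostInputs(
            self.costs.post_progression_per_cycle,
            self.costs.hospitalization_per_cycle,
            tuple(AdverseEvent(a.name, a.incidence, a.unit_cost)
                  for a in self.costs.adverse_events[arm]),
        )

    def pap_schedule(self) -> PAPSchedule:
        return PAPSchedule(tuple(tuple(t) for t in self.pap_tiers))

    def survival_model(self, scenario: str, arm: str, endpoint: str) -> ParametricSurvival:
        s = self.scenarios[scenario].survival[arm][endpoint]
        return ParametricSurvival(s.family, tuple(s.params))


def load_config(path) -> ModelConfig:
    """Load and validate a YAML config; errors name the offending field."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping, got {type(raw).__name__}")
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def default_config() -> ModelConfig:
    """The shipped configuration encoding the published model inputs."""
    text = resources.files("psmcea").joinpath("data/default_config.yaml").read_text()
    return ModelConfig.model_validate(yaml.safe_load(text))


def dump_config(config: ModelConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=False)
    )


def config_hash(config: ModelConfig) -> str:
    """Stable short hash of the fully resolved config, for output provenance."""
    blob = yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
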