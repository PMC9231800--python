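"""Run configuration: YAML schema, validation, defaults, serialization.

Every number the analysis needs lives in one config file per scenario.
Inputs the source model never published (expert-survey resource use,
adverse-event costs, the subsequent-treatment mix) are config-driven
placeholders flagged with ``source: placeholder``; the run manifest echoes
every such flag so no placeholder can silently masquerade as evidence.
"""

from __future__ import annotations

from importlib import resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import ArmSpec, CycleGrid
from .costing import CostConfig, DoseSchedule, PAPSchedule, VialSet
from .sensitivity import ParamSpec
from .survival import SurvivalCurve


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CurveSpec(_Strict):
    family: Literal[
        "exponential", "weibull", "lognormal", "loglogistic", "gompertz", "gengamma"
    ]
    params: list[float]
    source: Literal["published", "fitted"] = "published"

    def build(self, gengamma_sign: int) -> SurvivalCurve:
        p = list(self.params)
        if self.family == "gengamma":
            # config carries the published positive shape k; the sign switch
            # maps it to the signed Prentice shape Q
            p = [p[0], p[1], gengamma_sign * p[2]]
        return SurvivalCurve(self.family, tuple(p))


class ArmCurves(_Strict):
    ttp: CurveSpec
    pfs: CurveSpec
    pps: CurveSpec


class GridSpec(_Strict):
    first_cycle_days: float = 14.0
    later_cycle_days: float = 28.0
    phase_switch_months: float = 12.0
    horizon_months: float = 480.0

    def build(self) -> CycleGrid:
        return CycleGrid.build(
            self.first_cycle_days,
            self.later_cycle_days,
            self.phase_switch_months,
            self.horizon_months,
        )


class Conventions(_Strict):
    gengamma_sign: Literal[-1, 1] = -1
    half_cycle_correction: bool = False
    pps_clock: Literal["since_progression", "model_time"] = "since_progression"


class Utilities(_Strict):
    pf: float = 0.901
    pd: float = 0.863

    @model_validator(mode="after")
    def _range(self):
        if not (0 <= self.pd <= 1 and 0 <= self.pf <= 1):
            raise ValueError("utilities must lie in [0, 1]")
        return self


class DoseSpec(_Strict):
    dose_per_kg: float = 10.0
    body_weight: float = 61.2
    frequency_days: float = 14.0
    max_duration_months: float = 12.0

    def build(self) -> DoseSchedule:
        return DoseSchedule(
            self.dose_per_kg, self.body_weight, self.frequency_days, self.max_duration_months
        )


class VialSpec(_Strict):
    size_mg: float
    price: float = Field(gt=0)


class PapSpec(_Strict):
    stage1_paid: int = 2
    stage1_free: int = 2
    stage2_paid: int = 4

    def build(self) -> PAPSchedule:
        return PAPSchedule(self.stage1_paid, self.stage1_free, self.stage2_paid)


class CostItem(_Strict):
    value: float = Field(ge=0)
    source: Literal["paper", "placeholder"] = "placeholder"


class SubsequentItem(_Strict):
    label: str
    proportion: float = Field(ge=0, le=1)
    cost_per_cycle: float = Field(ge=0)
    source: Literal["paper", "placeholder"] = "placeholder"


class ArmCosts(_Strict):
    resource_pf_per_cycle: CostItem = CostItem(value=0.0)
    resource_pd_per_cycle: CostItem = CostItem(value=0.0)
    subsequent_mix: list[SubsequentItem] = []
    ae_cost_onceoff: CostItem = CostItem(value=0.0)
    terminal_care_cost: CostItem = CostItem(value=0.0)

    def build(self) -> CostConfig:
        placeholders = tuple(
            name
            for name, item in (
                ("resource_pf_per_cycle", self.resource_pf_per_cycle),
                ("resource_pd_per_cycle", self.resource_pd_per_cycle),
                ("ae_cost_onceoff", self.ae_cost_onceoff),
                ("terminal_care_cost", self.terminal_care_cost),
            )
            if item.source == "placeholder" and item.value != 0
        ) + tuple(
            f"subsequent:{s.label}" for s in self.subsequent_mix if s.source == "placeholder"
        )
        return CostConfig(
            resource_pf_per_cycle=self.resource_pf_per_cycle.value,
            resource_pd_per_cycle=self.resource_pd_per_cycle.value,
            subsequent_mix=tuple(
                (s.label, s.proportion, s.cost_per_cycle) for s in self.subsequent_mix
            ),
            ae_cost_onceoff=self.ae_cost_onceoff.value,
            terminal_care_cost=self.terminal_care_cost.value,
            placeholders=placeholders,
        )


class ParamEntry(_Strict):
    name: str
    base: float
    se: float = 0.0
    low: Optional[float] = None
    high: Optional[float] = None
    distribution: Literal["gamma", "beta", "normal", "uniform", "fixed"] = "fixed"

    def build(self) -> ParamSpec:
        return ParamSpec(self.name, self.base, self.se, self.low, self.high, self.distribution)


class PsaSettings(_Strict):
    n: int = 1000
    seed: int = 1


class RunConfig(_Strict):
    scenario: str = "base_case"
    pap: bool = False
    discount: float = Field(default=0.05, ge=0)
    wtp: float = 212_676.0
    grid: GridSpec = GridSpec()
    conventions: Conventions = Conventions()
    utilities: Utilities = Utilities()
    arms: dict[str, ArmCurves]
    dose: DoseSpec = DoseSpec()
    vials: list[VialSpec] = [
        VialSpec(size_mg=120.0, price=6066.0),
        VialSpec(size_mg=500.0, price=18088.0),
    ]
    pap_schedule: PapSpec = PapSpec()
    costs: dict[str, ArmCosts] = {}
    params: list[ParamEntry] = []
    psa: PsaSettings = PsaSettings()

    @model_validator(mode="after")
    def _arms_known(self):
        if set(self.arms) != {"durvalumab", "bsc"}:
            raise ValueError("arms must be exactly 'durvalumab' and 'bsc'")
        for arm in self.costs:
            if arm not in self.arms:
                raise ValueError(f"costs given for unknown arm {arm!r}")
        return self

    # -- builders -----------------------------------------------------------
    def build_arm(self, name: str) -> ArmSpec:
        curves = self.arms[name]
        sign = self.conventions.gengamma_sign
        return ArmSpec(
            name=name,
            ttp=curves.ttp.build(sign),
            pfs=curves.pfs.build(sign),
            pps=curves.pps.build(sign),
            utility_pf=self.utilities.pf,
            utility_pd=self.utilities.pd,
        )

    def build_vials(self) -> VialSet:
        return VialSet(tuple((v.size_mg, v.price) for v in self.vials))

    def build_costs(self, arm: str) -> CostConfig:
        return self.costs.get(arm, ArmCosts()).build()

    def param_specs(self) -> list[ParamSpec]:
        return [p.build() for p in self.params]

    def placeholder_report(self) -> list[str]:
        out = []
        for arm, ac in self.costs.items():
            for name in ac.build().placeholders:
                out.append(f"{arm}:{name}")
        return out


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def default_config(pap: bool = False) -> RunConfig:
    """The shipped base-case configuration (with or without PAP)."""
    name = "base_case_pap.yaml" if pap else "base_case.yaml"
    ref = resources.files("durvacea.data").joinpath(name)
    with resources.as_file(ref) as p:
        return load_config(p)
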