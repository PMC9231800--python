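"""Cost accrual: drug acquisition with vial optimization and the Patient
Assistance Program (PAP), per-cycle resource use, subsequent treatment,
adverse events and terminal care.  All currency in RMB.

The PAP for durvalumab is staged: the first two administrations are paid,
the next two are free, administrations five to eight are paid again, and
every later administration within the 12-month treatment window is free
as long as the patient remains progression-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTrace, CycleGrid, discount_factors, occupancy_for_accrual
from .survival import DAYS_PER_MONTH


class CostingError(ValueError):
    pass


@dataclass(frozen=True)
class DoseSchedule:
    dose_per_kg: float = 10.0  # mg/kg
    body_weight: float = 61.2  # kg
    frequency_days: float = 14.0
    max_duration_months: float = 12.0
    stop_on_progression: bool = True

    @property
    def dose_mg(self) -> float:
        d = self.dose_per_kg * self.body_weight
        if d <= 0:
            raise CostingError("dose must be positive")
        return d


@dataclass(frozen=True)
class VialSet:
    """Available vial sizes (mg) and unit prices (RMB)."""

    vials: tuple  # of (size_mg, price)

    def __post_init__(self):
        if not self.vials:
            raise CostingError("empty vial set")
        for size, price in self.vials:
            if size <= 0 or price <= 0:
                raise CostingError("vial sizes and prices must be positive")


DURVALUMAB_VIALS = VialSet(vials=((120.0, 6066.0), (500.0, 18088.0)))


@dataclass(frozen=True)
class PAPSchedule:
    stage1_paid: int = 2
    stage1_free: int = 2
    stage2_paid: int = 4
    # thereafter free until progression, within the treatment window

    def __post_init__(self):
        if min(self.stage1_paid, self.stage1_free, self.stage2_paid) < 0:
            raise CostingError("PAP counts must be non-negative")

    def is_paid(self, admin_index: int) -> bool:
        """Whether the 1-based administration is paid by the patient."""
        if admin_index <= self.stage1_paid:
            return True
        if admin_index <= self.stage1_paid + self.stage1_free:
            return False
        if admin_index <= self.stage1_paid + self.stage1_free + self.stage2_paid:
            return True
        return False


@dataclass
class CostConfig:
    """Non-drug cost inputs.  Values the source paper does not print ship as
    placeholders (flagged by ``placeholders``) and default to zero."""

    resource_pf_per_cycle: float = 0.0  # medical service + inspections, PF
    resource_pd_per_cycle: float = 0.0
    subsequent_mix: tuple = ()  # of (label, proportion, cost_per_cycle)
    ae_cost_onceoff: float = 0.0  # incidence-weighted expected AE cost
    terminal_care_cost: float = 0.0
    placeholders: tuple = ()

    def __post_init__(self):
        if any(c < 0 for c in (self.resource_pf_per_cycle, self.resource_pd_per_cycle,
                               self.ae_cost_onceoff, self.terminal_care_cost)):
            raise CostingError("costs must be non-negative")
        total_prop = sum(p for _, p, _ in self.subsequent_mix)
        if total_prop > 1 + 1e-9:
            raise CostingError("subsequent-treatment proportions exceed 1")

    @property
    def subsequent_per_cycle(self) -> float:
        return sum(p * c for _, p, c in self.subsequent_mix)


def administration_cost(dose_mg: float, vials: VialSet) -> float:
    """Cheapest combination of whole vials covering the dose (wastage paid)."""
    if dose_mg <= 0:
        raise CostingError("dose must be positive")
    sizes = [s for s, _ in vials.vials]
    prices = [p for _, p in vials.vials]
    min_size = min(sizes)
    max_counts = [math.ceil(dose_mg / min_size) for _ in sizes]

    best = math.inf

    def rec(idx: int, remaining: float, cost: float):
        nonlocal best
        if cost >= best:
            return
        if remaining <= 0:
            best = cost
            return
        if idx == len(sizes):
            return
        # try counts of vial idx from high to low
        hi = math.ceil(remaining / sizes[idx])
        for cnt in range(hi, -1, -1):
            rec(idx + 1, remaining - cnt * sizes[idx], cost + cnt * prices[idx])

    rec(0, dose_mg, 0.0)
    return best


def drug_cost_schedule(
    schedule: DoseSchedule,
    pap: PAPSchedule | None,
    grid: CycleGrid,
    vials: VialSet = DURVALUMAB_VIALS,
) -> np.ndarray:
    """Payable drug cost per cycle (to be weighted by PF occupancy).

    One administration per cycle while the cycle length matches the dosing
    frequency and the cycle starts within the treatment window.
    """
    b = grid.array
    widths_days = np.diff(b) * DAYS_PER_MONTH
    per_admin = administration_cost(schedule.dose_mg, vials)
    out = np.zeros(grid.n_cycles)
    admin_index = 0
    for i in range(grid.n_cycles):
        on_treatment = (
            b[i] < schedule.max_duration_months - 1e-9
            and abs(widths_days[i] - schedule.frequency_days) < 1e-6
        )
        if not on_treatment:
            continue
        admin_index += 1
        paid = pap.is_paid(admin_index) if pap is not None else True
        if paid:
            out[i] = per_admin
    if pap is not None and admin_index:
        min_paid = pap.stage1_paid + pap.stage2_paid
        if min_paid > admin_index:
            raise CostingError("PAP paid administrations exceed the treatment window")
    return out


@dataclass
class CostBreakdown:
    arm: str
    discount_rate: float
    drug: float
    resource_pf: float
    resource_pd: float
    subsequent: float
    ae: float
    terminal: float
    drug_undisc: float
    resource_pf_undisc: float
    resource_pd_undisc: float
    subsequent_undisc: float
    ae_undisc: float
    terminal_undisc: float

    @property
    def total(self) -> float:
        return self.drug + self.resource_pf + self.resource_pd + self.subsequent + self.ae + self.terminal

    @property
    def total_undisc(self) -> float:
        return (
            self.drug_undisc + self.resource_pf_undisc + self.resource_pd_undisc
            + self.subsequent_undisc + self.ae_undisc + self.terminal_undisc
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for disc, sfx in ((True, ""), (False, "_undisc")):
            rows.append(
                {
                    "arm": self.arm,
                    "discounted": disc,
                    "drug": getattr(self, "drug" + sfx),
                    "resource_pf": getattr(self, "resource_pf" + sfx),
                    "resource_pd": getattr(self, "resource_pd" + sfx),
                    "subsequent": getattr(self, "subsequent" + sfx),
                    "ae": getattr(self, "ae" + sfx),
                    "terminal": getattr(self, "terminal" + sfx),
                    "total": getattr(self, "total" + sfx),
                }
            )
        return pd.DataFrame(rows)


def accrue_costs(
    trace: CohortTrace,
    config: CostConfig,
    drug_vector: np.ndarray,
    discount: float,
    half_cycle_correction: bool = False,
    arm: str = "",
) -> CostBreakdown:
    """Occupancy-weighted, midpoint-discounted cost totals by component."""
    grid = trace.grid
    drug_vector = np.asarray(drug_vector, dtype=float)
    if drug_vector.shape != (grid.n_cycles,):
        raise CostingError("drug vector does not match the cycle grid")
    df = discount_factors(grid, discount)
    occ_pf = occupancy_for_accrual(trace.pf, half_cycle_correction)
    occ_pd = occupancy_for_accrual(trace.pd_total, half_cycle_correction)

    def comp(vec):
        return float(np.sum(vec * df)), float(np.sum(vec))

    drug_d, drug_u = comp(drug_vector * occ_pf)
    rpf_d, rpf_u = comp(config.resource_pf_per_cycle * occ_pf)
    rpd_d, rpd_u = comp(config.resource_pd_per_cycle * occ_pd)
    sub_d, sub_u = comp(config.subsequent_per_cycle * occ_pd)
    term_d, term_u = comp(config.terminal_care_cost * trace.incident_deaths)
    ae = config.ae_cost_onceoff  # one-off at model entry, undiscounted
    return CostBreakdown(
        arm=arm,
        discount_rate=discount,
        drug=drug_d,
        resource_pf=rpf_d,
        resource_pd=rpd_d,
        subsequent=sub_d,
        ae=ae,
        terminal=term_d,
        drug_undisc=drug_u,
        resource_pf_undisc=rpf_u,
        resource_pd_undisc=rpd_u,
        subsequent_undisc=sub_u,
        ae_undisc=ae,
        terminal_undisc=term_u,
    )
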