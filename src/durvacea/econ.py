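"""Comparative outcomes: increments, ICER, net monetary benefit, WTP decision."""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import EconResult

#: 3x Chinese 2019 GDP per capita, RMB per QALY
DEFAULT_WTP = 212_676.0


@dataclass
class Comparison:
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None
    label: str  # "", "dominant", "dominated", "undefined ICER"
    wtp: float
    cost_effective: bool


def compare(
    intervention: EconResult,
    comparator: EconResult,
    cost_intervention: float,
    cost_comparator: float,
    wtp: float = DEFAULT_WTP,
) -> Comparison:
    """Incremental cost-effectiveness of intervention vs comparator.

    ICER = dCost/dQALY when dQALY > 0; otherwise a dominance label is used
    ('dominant' for cheaper-and-better, 'dominated' for costlier-and-worse,
    'undefined ICER' when dQALY vanishes with a nonzero cost difference).
    """
    if abs(intervention.discount_rate - comparator.discount_rate) > 1e-12:
        raise ValueError("arms computed at different discount rates")
    d_cost = cost_intervention - cost_comparator
    d_qaly = intervention.qaly_total - comparator.qaly_total
    d_ly = intervention.ly_total - comparator.ly_total

    icer: float | None = None
    label = ""
    if abs(d_qaly) < 1e-9:
        label = "undefined ICER" if abs(d_cost) > 0 else "undefined ICER"
    elif d_cost < 0 and d_qaly > 0:
        label = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        label = "dominated"
    else:
        icer = d_cost / d_qaly
    cost_effective = label == "dominant" or (icer is not None and d_qaly > 0 and icer <= wtp)
    return Comparison(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        icer=icer,
        label=label,
        wtp=wtp,
        cost_effective=cost_effective,
    )


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit: wtp * dQALY - dCost."""
    return wtp * delta_qaly - delta_cost
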