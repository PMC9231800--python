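"""Three-state (PF / PD / death) semi-Markov cohort simulation.

The progression-free (PF) state empties according to the PFS curve; the
share of each cycle's PF exits that progress rather than die is taken from
the TTP curve (PF->death probability = PFS exit minus TTP exit, floored at
zero).  Progressors enter PD with a tunnel clock that by default restarts
at progression, so each PD sub-cohort dies according to the PPS curve
evaluated on time-since-progression.  Life-years accrue as occupancy x
cycle length, QALYs additionally weight by the state utility, and
discounting applies a factor (1+r)^(-t_mid/12) at each cycle midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import DAYS_PER_MONTH, SurvivalCurve, survival


class CohortError(RuntimeError):
    pass


@dataclass(frozen=True)
class CycleGrid:
    """Cycle boundaries in months: short cycles first, longer cycles after."""

    boundaries: tuple

    @classmethod
    def build(
        cls,
        first_cycle_days: float = 14.0,
        later_cycle_days: float = 28.0,
        phase_switch_months: float = 12.0,
        horizon_months: float = 480.0,
    ) -> "CycleGrid":
        if first_cycle_days <= 0 or later_cycle_days <= 0:
            raise ValueError("cycle lengths must be positive")
        if horizon_months <= phase_switch_months:
            raise ValueError("horizon must exceed the phase switch")
        n1 = int(round(phase_switch_months * DAYS_PER_MONTH / first_cycle_days))
        d1 = first_cycle_days / DAYS_PER_MONTH
        d2 = later_cycle_days / DAYS_PER_MONTH
        b = [i * d1 for i in range(n1 + 1)]
        while b[-1] < horizon_months:
            b.append(b[-1] + d2)
        return cls(boundaries=tuple(b))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.boundaries, dtype=float)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def widths(self) -> np.ndarray:
        return np.diff(self.array)

    def midpoints(self) -> np.ndarray:
        b = self.array
        return (b[:-1] + b[1:]) / 2


@dataclass(frozen=True)
class ArmSpec:
    """One comparator arm: its three curves and state utilities."""

    name: str
    ttp: SurvivalCurve
    pfs: SurvivalCurve
    pps: SurvivalCurve
    utility_pf: float = 0.901
    utility_pd: float = 0.863

    def __post_init__(self):
        if not (0 <= self.utility_pd <= 1 and 0 <= self.utility_pf <= 1):
            raise ValueError("utilities must lie in [0, 1]")
        if self.utility_pd > self.utility_pf:
            import warnings

            warnings.warn("PD utility exceeds PF utility")


@dataclass
class CohortTrace:
    """State occupancy at every cycle boundary plus per-cycle incidence."""

    grid: CycleGrid
    pf: np.ndarray  # boundary-indexed, length n+1
    pd_by_tunnel: np.ndarray  # [boundary, entry-cycle] lower-triangular
    dead: np.ndarray  # boundary-indexed
    incident_deaths: np.ndarray  # cycle-indexed, length n
    incident_progressions: np.ndarray  # cycle-indexed

    @property
    def pd_total(self) -> np.ndarray:
        return self.pd_by_tunnel.sum(axis=1)

    def validate(self, tol: float = 1e-10) -> None:
        total = self.pf + self.pd_total + self.dead
        if np.max(np.abs(total - 1.0)) > tol:
            raise CohortError("state occupancies do not sum to 1")
        if np.min(self.pf) < -1e-12 or np.min(self.pd_by_tunnel) < -1e-12:
            raise CohortError("negative occupancy")
        if np.min(np.diff(self.dead)) < -1e-12:
            raise CohortError("cumulative deaths decreased")


@dataclass
class EconResult:
    """Discounted and undiscounted LY/QALY, split by state (years)."""

    arm: str
    discount_rate: float
    ly_pf: float
    ly_pd: float
    qaly_pf: float
    qaly_pd: float
    ly_pf_undisc: float
    ly_pd_undisc: float
    qaly_pf_undisc: float
    qaly_pd_undisc: float

    @property
    def ly_total(self) -> float:
        return self.ly_pf + self.ly_pd

    @property
    def qaly_total(self) -> float:
        return self.qaly_pf + self.qaly_pd

    @property
    def ly_total_undisc(self) -> float:
        return self.ly_pf_undisc + self.ly_pd_undisc

    @property
    def qaly_total_undisc(self) -> float:
        return self.qaly_pf_undisc + self.qaly_pd_undisc

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for disc, sfx in ((True, ""), (False, "_undisc")):
            rows.append(
                {
                    "arm": self.arm,
                    "discounted": disc,
                    "ly_pf": getattr(self, "ly_pf" + sfx),
                    "ly_pd": getattr(self, "ly_pd" + sfx),
                    "ly_total": getattr(self, "ly_total" + sfx),
                    "qaly_pf": getattr(self, "qaly_pf" + sfx),
                    "qaly_pd": getattr(self, "qaly_pd" + sfx),
                    "qaly_total": getattr(self, "qaly_total" + sfx),
                }
            )
        return pd.DataFrame(rows)


def run_cohort(
    arm: ArmSpec,
    grid: CycleGrid,
    discount: float = 0.05,
    half_cycle_correction: bool = False,
    pps_clock: str = "since_progression",
) -> tuple[CohortTrace, EconResult]:
    """Run the cohort through the grid and accrue (Q)ALYs.

    ``pps_clock`` selects whether the PD->death curve is evaluated on time
    since progression (tunnel reset, the default) or on model time.
    """
    if discount < 0:
        raise ValueError("discount must be >= 0")
    if pps_clock not in ("since_progression", "model_time"):
        raise ValueError("pps_clock must be 'since_progression' or 'model_time'")

    b = grid.array
    n = grid.n_cycles
    s_pfs = np.maximum(np.atleast_1d(survival(arm.pfs, b)), 0.0)
    s_ttp = np.maximum(np.atleast_1d(survival(arm.ttp, b)), 0.0)

    pf = np.empty(n + 1)
    pf[0] = 1.0
    new_pd = np.zeros(n)
    deaths_from_pf = np.zeros(n)
    for i in range(n):
        if s_pfs[i] <= 0:
            p_leave = 1.0
        else:
            p_leave = 1.0 - s_pfs[i + 1] / s_pfs[i]
        if s_ttp[i] <= 0:
            p_prog = 1.0
        else:
            p_prog = 1.0 - s_ttp[i + 1] / s_ttp[i]
        p_prog_eff = min(p_prog, p_leave)
        new_pd[i] = pf[i] * p_prog_eff
        deaths_from_pf[i] = pf[i] * (p_leave - p_prog_eff)
        pf[i + 1] = pf[i] * (1.0 - p_leave)
        if pf[i + 1] < -1e-12:
            raise CohortError(f"negative PF occupancy at cycle {i}")
        pf[i + 1] = max(pf[i + 1], 0.0)

    # PD tunnel occupancy: entrants of cycle j appear at boundary j+1 with
    # elapsed time 0; the per-cycle PPS ratios telescope, so the mass of
    # entry-cohort j at boundary i is new_pd[j] * S_pps(t_i - t_{j+1})
    # (or S_pps(t_i)/S_pps(t_{j+1}) on the model-time clock).
    entry_t = b[1:]  # entry boundary of each cycle's progressors
    pd_by_tunnel = np.zeros((n + 1, n))
    # elapsed[i, j] for boundaries i >= j+1
    ii, jj = np.tril_indices(n + 1, k=-1)  # i > j ; cohort j exists from boundary j+1
    if len(ii):
        if pps_clock == "since_progression":
            elapsed = b[ii] - entry_t[jj]
            ratios = np.atleast_1d(survival(arm.pps, np.maximum(elapsed, 0.0)))
        else:
            s_b = np.maximum(np.atleast_1d(survival(arm.pps, b)), 1e-300)
            ratios = s_b[ii] / s_b[jj + 1]
        pd_by_tunnel[ii, jj] = new_pd[jj] * np.minimum(ratios, 1.0)

    pd_total = pd_by_tunnel.sum(axis=1)
    dead = 1.0 - pf - pd_total
    dead = np.maximum(dead, 0.0)

    deaths_from_pd = np.maximum(
        (pd_total[:-1] + new_pd) - pd_total[1:], 0.0
    )  # entrants counted at next boundary
    incident_deaths = deaths_from_pf + deaths_from_pd

    trace = CohortTrace(
        grid=grid,
        pf=pf,
        pd_by_tunnel=pd_by_tunnel,
        dead=dead,
        incident_deaths=incident_deaths,
        incident_progressions=new_pd.copy(),
    )
    trace.validate()
    econ = accrue_health(trace, arm, discount, half_cycle_correction)
    return trace, econ


def occupancy_for_accrual(
    values: np.ndarray, half_cycle_correction: bool
) -> np.ndarray:
    """Per-cycle occupancy from boundary values (start-of-cycle or averaged)."""
    if half_cycle_correction:
        return (values[:-1] + values[1:]) / 2.0
    return values[:-1]


def discount_factors(grid: CycleGrid, rate: float) -> np.ndarray:
    return (1.0 + rate) ** (-grid.midpoints() / 12.0)


def accrue_health(
    trace: CohortTrace,
    arm: ArmSpec,
    discount: float,
    half_cycle_correction: bool = False,
) -> EconResult:
    grid = trace.grid
    dt_years = grid.widths() / 12.0
    df = discount_factors(grid, discount)
    occ_pf = occupancy_for_accrual(trace.pf, half_cycle_correction)
    occ_pd = occupancy_for_accrual(trace.pd_total, half_cycle_correction)

    def tot(occ, w):
        return float(np.sum(occ * dt_years * w))

    return EconResult(
        arm=arm.name,
        discount_rate=discount,
        ly_pf=tot(occ_pf, df),
        ly_pd=tot(occ_pd, df),
        qaly_pf=tot(occ_pf, df) * arm.utility_pf,
        qaly_pd=tot(occ_pd, df) * arm.utility_pd,
        ly_pf_undisc=tot(occ_pf, 1.0),
        ly_pd_undisc=tot(occ_pd, 1.0),
        qaly_pf_undisc=tot(occ_pf, 1.0) * arm.utility_pf,
        qaly_pd_undisc=tot(occ_pd, 1.0) * arm.utility_pd,
    )


def trace_to_csv(trace: CohortTrace, path) -> None:
    df = trace_to_frame(trace)
    df.to_csv(path, index=False)


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    b = trace.grid.array
    n = trace.grid.n_cycles
    return pd.DataFrame(
        {
            "time": b[:-1],
            "pf": trace.pf[:-1],
            "pd_total": trace.pd_total[:-1],
            "dead": trace.dead[:-1],
            "incident_deaths": trace.incident_deaths,
            "incident_progressions": trace.incident_progressions,
        }
    )


def trace_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time", "pf", "pd_total", "dead", "incident_deaths", "incident_progressions"}
    if not required.issubset(df.columns):
        raise CohortError("malformed trace CSV")
    return df
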