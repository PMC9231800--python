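"""Synthetic individual patient data (IPD) and longitudinal utilities.

The patient-level trial data behind the model are not public, so this
module generates stand-ins with the statistical structure the analysis
assumes: progression times from the TTP curve, pre-progression death via
the PFS-minus-TTP excess hazard (so the min structure reproduces the PFS
exit intensity), post-progression survival from the PPS curve, plus
EQ-5D-style utility observations clustered by patient with state-specific
means.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import IPDRecord, SurvivalCurve, hazard, survival


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_patients: int = 2000
    ttp: SurvivalCurve | None = None
    pfs: SurvivalCurve | None = None
    pps: SurvivalCurve | None = None
    censor_time: float = 60.0  # months, administrative
    utility_pf: float = 0.901
    utility_pd: float = 0.863
    sd_between: float = 0.05  # patient random intercept SD
    sd_residual: float = 0.05
    assessment_interval: float = 1.5  # months
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise SimulationError("n_patients must be >= 1")
        if self.censor_time <= 0:
            raise SimulationError("censor time must be positive")
        if self.sd_between < 0 or self.sd_residual < 0:
            raise SimulationError("SDs must be >= 0")
        if not (0 <= self.utility_pd <= 1 and 0 <= self.utility_pf <= 1):
            raise SimulationError("utility means must be in [0,1]")


def sample_survival_times(
    curve: SurvivalCurve, n: int, rng: np.random.Generator, t_max: float = 1e6
) -> np.ndarray:
    """Inverse-CDF sampling via a monotone log-spaced grid of S(t)."""
    grid = np.concatenate([[0.0], np.logspace(-6, np.log10(t_max), 4000)])
    s = np.atleast_1d(survival(curve, grid))
    s = np.minimum.accumulate(s)  # enforce monotonicity against rounding
    u = rng.uniform(size=n)
    # S decreasing: interpolate t as a function of S
    t = np.interp(u, s[::-1], grid[::-1])
    # draws in the tail beyond t_max are truncated at t_max (heavy-tail guard)
    return t


def _excess_death_times(
    pfs: SurvivalCurve, ttp: SurvivalCurve, n: int, rng: np.random.Generator, t_max: float
) -> np.ndarray:
    """Pre-progression death times from hazard max(0, h_pfs - h_ttp).

    Sampled by inverting the cumulative excess hazard on a fine grid.
    """
    # cap the grid where PFS survival is numerically exhausted (no PF left)
    probe = np.concatenate([[0.0], np.logspace(-6, np.log10(t_max), 500)])
    s_probe = np.atleast_1d(survival(pfs, probe))
    alive = probe[s_probe > 1e-10]
    t_hi = float(alive[-1]) if len(alive) else t_max
    grid = np.linspace(1e-6, min(t_hi, t_max), 4001)
    h = np.maximum(
        np.atleast_1d(hazard(pfs, grid)) - np.atleast_1d(hazard(ttp, grid)), 0.0
    )
    ch = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(grid))])
    e = rng.exponential(size=n)
    t = np.interp(e, ch, grid, right=np.inf)  # beyond grid: no death event
    return t


def validate_curve_consistency(
    pfs: SurvivalCurve, ttp: SurvivalCurve, t_max: float, tol: float = 1e-3
) -> None:
    """PFS survival must not exceed TTP survival (negative death hazard)."""
    grid = np.linspace(0.01, t_max, 500)
    d = np.atleast_1d(survival(pfs, grid)) - np.atleast_1d(survival(ttp, grid))
    bad = d > tol
    if np.any(bad):
        t_bad = grid[bad][0]
        raise SimulationError(
            f"PFS survival exceeds TTP survival at t = {t_bad:.2f} months"
        )


def simulate_ipd(config: SimConfig) -> tuple[dict, pd.DataFrame]:
    """Simulate one arm's IPD.

    Returns ``(records, patients)`` where ``records`` maps role ('ttp',
    'pfs', 'pps') to lists of :class:`IPDRecord` with administrative
    right-censoring applied, and ``patients`` is the underlying per-patient
    frame (true progression/death times) used by the utility simulator.
    """
    if config.ttp is None or config.pfs is None or config.pps is None:
        raise SimulationError("ttp, pfs and pps curves are all required")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    c = config.censor_time
    t_max = max(10 * c, 240.0)
    validate_curve_consistency(config.pfs, config.ttp, t_max)

    t_prog = sample_survival_times(config.ttp, n, rng, t_max)
    t_death_pre = _excess_death_times(config.pfs, config.ttp, n, rng, t_max)
    progressed = t_prog < t_death_pre
    t_exit = np.minimum(t_prog, t_death_pre)  # PFS event time
    t_pps = sample_survival_times(config.pps, n, rng, t_max)
    t_death = np.where(progressed, t_prog + t_pps, t_death_pre)

    records: dict[str, list[IPDRecord]] = {"ttp": [], "pfs": [], "pps": []}
    for i in range(n):
        # TTP: progression as the event; death before progression censors
        obs = min(t_prog[i], t_death_pre[i], c)
        records["ttp"].append(IPDRecord(obs, int(progressed[i] and t_prog[i] <= c)))
        # PFS: any exit from PF as the event
        records["pfs"].append(IPDRecord(min(t_exit[i], c), int(t_exit[i] <= c)))
        # PPS: only observed progressors contribute, clocked from progression
        if progressed[i] and t_prog[i] <= c:
            obs_pps = min(t_pps[i], c - t_prog[i])
            records["pps"].append(IPDRecord(obs_pps, int(t_pps[i] <= c - t_prog[i])))

    patients = pd.DataFrame(
        {
            "patient": np.arange(n),
            "t_prog": np.where(progressed, t_prog, np.inf),
            "t_death": t_death,
            "censor": c,
        }
    )
    return records, patients


def simulate_utilities(config: SimConfig, patients: pd.DataFrame) -> pd.DataFrame:
    """Longitudinal utility observations at the assessment schedule.

    observation = state mean + patient intercept + residual, clamped to the
    instrument range [-0.5, 1].
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    intercepts = rng.normal(0.0, config.sd_between, size=len(patients))
    for idx, row in enumerate(patients.itertuples()):
        t = config.assessment_interval
        while t <= min(row.t_death, row.censor):
            state = "PD" if t >= row.t_prog else "PF"
            mean = config.utility_pd if state == "PD" else config.utility_pf
            val = mean + intercepts[idx] + rng.normal(0.0, config.sd_residual)
            rows.append(
                {
                    "patient": row.patient,
                    "time": t,
                    "state": state,
                    "value": float(np.clip(val, -0.5, 1.0)),
                }
            )
            t += config.assessment_interval
    return pd.DataFrame(rows, columns=["patient", "time", "state", "value"])


@dataclass
class UtilityEstimate:
    mean_pf: float | None
    mean_pd: float | None
    se_pf: float | None
    se_pd: float | None
    method: str = "mixedlm"


def estimate_state_utilities(observations: pd.DataFrame) -> UtilityEstimate:
    """State-mean utilities with a patient random intercept.

    Fits a two-level linear mixed model (state fixed effects, patient
    intercepts) via statsmodels MixedLM; with (near-)zero residual noise
    the mixed model is singular and the estimator falls back to plain state
    means with patient-clustered standard errors.
    """
    obs = observations
    if obs["patient"].nunique() < 2:
        raise SimulationError("need at least 2 patients")
    present = set(obs["state"].unique())
    out = {"PF": (None, None), "PD": (None, None)}
    within_state_sd = obs.groupby("state")["value"].std(ddof=0).max()
    if within_state_sd < 1e-9 or len(present) < 2:
        # degenerate or single-state data: plain means
        for st in present:
            v = obs.loc[obs.state == st, "value"]
            out[st] = (float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0)
        return UtilityEstimate(
            out["PF"][0], out["PD"][0], out["PF"][1], out["PD"][1], method="means"
        )
    import statsmodels.formula.api as smf

    try:
        model = smf.mixedlm("value ~ 0 + C(state)", obs, groups=obs["patient"])
        fit = model.fit(reml=True, method="lbfgs")
        names = list(fit.fe_params.index)
        for st in ("PD", "PF"):
            key = f"C(state)[{st}]"
            if key in names:
                out[st] = (float(fit.fe_params[key]), float(fit.bse_fe[key]))
        method = "mixedlm"
    except Exception:
        for st in present:
            sub = obs[obs.state == st]
            pm = sub.groupby("patient")["value"].mean()
            out[st] = (float(pm.mean()), float(pm.std(ddof=1) / np.sqrt(len(pm))))
        method = "cluster-means"
    return UtilityEstimate(out["PF"][0], out["PD"][0], out["PF"][1], out["PD"][1], method)


def write_utilities_csv(observations: pd.DataFrame, path) -> None:
    observations.to_csv(path, index=False)
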