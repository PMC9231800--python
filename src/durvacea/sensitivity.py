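"""One-way (tornado) and probabilistic sensitivity analysis.

Distributions follow common HTA practice: gamma and beta parameters are
moment-matched to the stated mean and standard error, normal and uniform
are used as given, and 'fixed' parameters never vary.  The model runner
abstraction maps a parameter dictionary to incremental outcomes, so both
analyses re-evaluate the full pipeline per perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .econ import nmb


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class ParamSpec:
    name: str
    base: float
    se: float = 0.0
    low: float | None = None
    high: float | None = None
    distribution: str = "fixed"  # gamma | beta | normal | uniform | fixed

    def __post_init__(self):
        if self.distribution not in ("gamma", "beta", "normal", "uniform", "fixed"):
            raise SensitivityError(f"{self.name}: unknown distribution")
        if self.se < 0:
            raise SensitivityError(f"{self.name}: SE must be >= 0")
        if self.distribution == "beta" and not (0 <= self.base <= 1):
            raise SensitivityError(f"{self.name}: beta requires base in [0,1]")
        lo, hi = self.bounds()
        if not lo <= self.base <= hi:
            raise SensitivityError(f"{self.name}: base outside [low, high]")

    def bounds(self) -> tuple[float, float]:
        """OWSA bounds: stated range, else mean +/- 1.96 SE."""
        lo = self.low if self.low is not None else self.base - 1.96 * self.se
        hi = self.high if self.high is not None else self.base + 1.96 * self.se
        return lo, hi


#: a model runner maps {param name: value} -> (delta_cost, delta_qaly)
ModelRunner = Callable[[dict], tuple[float, float]]


def sample_params(
    params: Sequence[ParamSpec], n: int, seed: int | np.random.Generator
) -> list[dict]:
    """Draw ``n`` joint parameter maps (independent across parameters)."""
    if n < 1:
        raise SensitivityError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {}
    for p in params:
        if p.distribution == "fixed" or (p.se == 0 and p.distribution != "uniform"):
            cols[p.name] = np.full(n, p.base)
        elif p.distribution == "gamma":
            shape = (p.base / p.se) ** 2
            scale = p.se**2 / p.base
            cols[p.name] = rng.gamma(shape, scale, size=n)
        elif p.distribution == "beta":
            m, v = p.base, p.se**2
            if v >= m * (1 - m):
                raise SensitivityError(f"{p.name}: SE too large for beta moment matching")
            k = m * (1 - m) / v - 1
            cols[p.name] = np.clip(rng.beta(m * k, (1 - m) * k, size=n), 0.0, 1.0)
        elif p.distribution == "normal":
            cols[p.name] = rng.normal(p.base, p.se, size=n)
        elif p.distribution == "uniform":
            lo, hi = p.bounds()
            cols[p.name] = rng.uniform(lo, hi, size=n)
    return [{k: float(v[i]) for k, v in cols.items()} for i in range(n)]


def owsa(params: Sequence[ParamSpec], runner: ModelRunner) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high bound, others at base.

    Perturbations that make dQALY <= 0 are flagged, not dropped.
    """
    base_map = {p.name: p.base for p in params}
    rows = []
    for p in params:
        lo, hi = p.bounds()
        vals = {}
        flagged = False
        for tag, v in (("icer_low", lo), ("icer_high", hi)):
            m = dict(base_map)
            m[p.name] = v
            d_cost, d_qaly = runner(m)
            if d_qaly <= 1e-12:
                vals[tag] = math.nan
                flagged = True
            else:
                vals[tag] = d_cost / d_qaly
        swing = (
            abs(vals["icer_high"] - vals["icer_low"])
            if not flagged
            else math.inf  # keep flagged rows visible at the top
        )
        rows.append(
            {
                "parameter": p.name,
                "low": lo,
                "high": hi,
                "icer_low": vals["icer_low"],
                "icer_high": vals["icer_high"],
                "swing": 0.0 if (lo == hi) else swing,
                "flag": "dominated/undefined" if flagged else "",
            }
        )
    df = pd.DataFrame(rows).sort_values("swing", ascending=False, kind="stable")
    return df.reset_index(drop=True)


@dataclass
class PsaSample:
    draw: int
    params: dict
    delta_cost: float
    delta_qaly: float


@dataclass
class PsaResult:
    samples: list
    failures: list
    mean_delta_cost: float
    mean_delta_qaly: float
    icer: float | None  # ratio of means
    prob_cost_effective: float
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": [s.draw for s in self.samples],
                "delta_cost": [s.delta_cost for s in self.samples],
                "delta_qaly": [s.delta_qaly for s in self.samples],
            }
        )


def run_psa(
    params: Sequence[ParamSpec],
    runner: ModelRunner,
    n: int = 1000,
    seed: int = 0,
    wtp: float = 212_676.0,
) -> PsaResult:
    """Monte-Carlo PSA: n joint draws, full model evaluation per draw.

    The summary ICER is the ratio of mean increments (mean dCost over mean
    dQALY); the probability of cost-effectiveness is the fraction of draws
    with positive net monetary benefit at ``wtp``.
    """
    maps = sample_params(params, n, seed)
    samples: list[PsaSample] = []
    failures = []
    for i, m in enumerate(maps):
        try:
            d_cost, d_qaly = runner(m)
            if not (math.isfinite(d_cost) and math.isfinite(d_qaly)):
                raise ValueError("non-finite outcome")
            samples.append(PsaSample(i, m, d_cost, d_qaly))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            failures.append((i, str(exc)))
    if len(failures) > 0.01 * n:
        raise SensitivityError(f"{len(failures)} of {n} PSA draws failed")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    mean_dc, mean_dq = float(dc.mean()), float(dq.mean())
    icer = mean_dc / mean_dq if abs(mean_dq) > 1e-12 else None
    prob = float(np.mean(wtp * dq - dc > 0))
    return PsaResult(samples, failures, mean_dc, mean_dq, icer, prob, wtp)


def ceac(samples: Sequence[PsaSample], wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise SensitivityError("empty WTP grid")
    if np.any(wtp_grid < 0):
        raise SensitivityError("WTP grid must be non-negative")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    probs = [float(np.mean(l * dq - dc > 0)) for l in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})


def default_wtp_grid() -> np.ndarray:
    """0 to 400,000 RMB in 2,000-RMB steps."""
    return np.arange(0.0, 400_001.0, 2_000.0)
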