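"""Pipeline orchestration: base case, OWSA and PSA runs with file outputs.

The state-occupancy traces depend only on the curves, grid and PPS clock,
none of which are sampled in sensitivity analyses, so traces are computed
once per arm and re-valued (utilities, discounting, prices) per draw.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import ArmSpec, accrue_health, run_cohort
from .config import RunConfig, dump_config
from .costing import VialSet, accrue_costs, drug_cost_schedule
from .econ import Comparison, compare
from .sensitivity import ceac, default_wtp_grid, owsa, run_psa

log = logging.getLogger("durvacea")

ARMS = ("durvalumab", "bsc")


def build_traces(config: RunConfig) -> dict:
    """One cohort trace per arm under the config's conventions."""
    out = {}
    for arm_name in ARMS:
        arm = config.build_arm(arm_name)
        trace, _ = run_cohort(
            arm,
            config.grid.build(),
            discount=config.discount,
            half_cycle_correction=config.conventions.half_cycle_correction,
            pps_clock=config.conventions.pps_clock,
        )
        out[arm_name] = trace
    return out


def _apply_overrides(config: RunConfig, overrides: dict | None):
    """Resolve sampled/base parameter values into model inputs."""
    ov = overrides or {}
    discount = float(ov.get("discount_rate", config.discount))
    u_pf = float(ov.get("utility_pf", config.utilities.pf))
    u_pd = float(ov.get("utility_pd", config.utilities.pd))
    vials = []
    for v in config.vials:
        price = v.price
        if v.size_mg == 120.0:
            price = float(ov.get("durvalumab_120_price", price))
        elif v.size_mg == 500.0:
            price = float(ov.get("durvalumab_500_price", price))
        vials.append((v.size_mg, price))
    cost_cfgs = {}
    for arm_name in ARMS:
        cc = config.build_costs(arm_name)
        cc = dataclasses.replace(
            cc,
            resource_pf_per_cycle=float(ov.get("resource_pf_per_cycle", cc.resource_pf_per_cycle)),
            resource_pd_per_cycle=float(ov.get("resource_pd_per_cycle", cc.resource_pd_per_cycle)),
            terminal_care_cost=float(ov.get("terminal_care_cost", cc.terminal_care_cost)),
        )
        cost_cfgs[arm_name] = cc
    return discount, u_pf, u_pd, VialSet(tuple(vials)), cost_cfgs


def evaluate(
    config: RunConfig, traces: dict | None = None, overrides: dict | None = None
) -> dict:
    """Full valuation of both arms plus their comparison.

    Returns a dict with per-arm EconResult and CostBreakdown objects and the
    durvalumab-vs-BSC :class:`Comparison`.
    """
    if traces is None:
        traces = build_traces(config)
    discount, u_pf, u_pd, vials, cost_cfgs = _apply_overrides(config, overrides)
    hcc = config.conventions.half_cycle_correction
    grid = config.grid.build()
    econ, costs = {}, {}
    for arm_name in ARMS:
        arm = dataclasses.replace(
            config.build_arm(arm_name), utility_pf=u_pf, utility_pd=u_pd
        )
        trace = traces[arm_name]
        econ[arm_name] = accrue_health(trace, arm, discount, hcc)
        if arm_name == "durvalumab":
            pap = config.pap_schedule.build() if config.pap else None
            drug_vec = drug_cost_schedule(config.dose.build(), pap, grid, vials)
        else:
            drug_vec = np.zeros(grid.n_cycles)  # placebo arm: no drug cost
        costs[arm_name] = accrue_costs(
            trace, cost_cfgs[arm_name], drug_vec, discount, hcc, arm=arm_name
        )
    comparison = compare(
        econ["durvalumab"],
        econ["bsc"],
        costs["durvalumab"].total,
        costs["bsc"].total,
        wtp=config.wtp,
    )
    return {"econ": econ, "costs": costs, "comparison": comparison, "traces": traces}


def make_runner(config: RunConfig, traces: dict | None = None):
    """A model runner (param map -> (dCost, dQALY)) for OWSA/PSA."""
    if traces is None:
        traces = build_traces(config)

    def runner(param_map: dict) -> tuple[float, float]:
        res = evaluate(config, traces, param_map)
        c: Comparison = res["comparison"]
        return c.delta_cost, c.delta_qaly

    return runner


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, outdir: Path, extra: dict | None = None) -> None:
    manifest = {
        "scenario": config.scenario,
        "config_hash": _config_hash(config),
        "version": __version__,
        "pap": config.pap,
        "conventions": config.conventions.model_dump(),
        "psa_seed": config.psa.seed,
        "placeholders": config.placeholder_report(),
    }
    manifest.update(extra or {})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _prepare_outdir(outdir) -> Path:
    outdir = Path(outdir)
    if not outdir.exists():
        outdir.mkdir(parents=True)
        log.info("created output directory %s", outdir)
    return outdir


def run_base_case(config: RunConfig, outdir) -> dict:
    """Base-case run: traces, econ results, cost components, comparison."""
    outdir = _prepare_outdir(outdir)
    res = evaluate(config)
    from .cohort import trace_to_csv

    for arm_name, trace in res["traces"].items():
        trace_to_csv(trace, outdir / f"trace_{arm_name}.csv")
    pd.concat([e.to_frame() for e in res["econ"].values()]).to_csv(
        outdir / "econ_results.csv", index=False
    )
    pd.concat([c.to_frame() for c in res["costs"].values()]).to_csv(
        outdir / "costs.csv", index=False
    )
    c = res["comparison"]
    pd.DataFrame(
        [
            {
                "delta_cost": c.delta_cost,
                "delta_qaly": c.delta_qaly,
                "delta_ly": c.delta_ly,
                "icer": c.icer if c.icer is not None else "",
                "label": c.label,
                "wtp": c.wtp,
                "cost_effective": c.cost_effective,
            }
        ]
    ).to_csv(outdir / "comparison.csv", index=False, float_format="%.2f")
    write_manifest(config, outdir)
    dump_config(config, outdir / "config_resolved.yaml")
    for ph in config.placeholder_report():
        log.warning("placeholder input in effect: %s", ph)
    return res


def run_owsa(config: RunConfig, outdir) -> pd.DataFrame:
    outdir = _prepare_outdir(outdir)
    runner = make_runner(config)
    table = owsa(config.param_specs(), runner)
    table.to_csv(outdir / "tornado.csv", index=False)
    write_manifest(config, outdir, {"analysis": "owsa"})
    return table


def run_probabilistic(config: RunConfig, outdir, n: int | None = None, seed: int | None = None):
    outdir = _prepare_outdir(outdir)
    n = n or config.psa.n
    seed = config.psa.seed if seed is None else seed
    runner = make_runner(config)
    result = run_psa(config.param_specs(), runner, n=n, seed=seed, wtp=config.wtp)
    result.to_frame().to_csv(outdir / "psa_samples.csv", index=False)
    ceac_table = ceac(result.samples, default_wtp_grid())
    ceac_table.to_csv(outdir / "ceac.csv", index=False)
    pd.DataFrame(
        [
            {
                "n": len(result.samples),
                "mean_delta_cost": result.mean_delta_cost,
                "mean_delta_qaly": result.mean_delta_qaly,
                "icer_ratio_of_means": result.icer,
                "prob_cost_effective": result.prob_cost_effective,
                "wtp": result.wtp,
                "failures": len(result.failures),
            }
        ]
    ).to_csv(outdir / "psa_summary.csv", index=False)
    write_manifest(config, outdir, {"analysis": "psa", "n": n, "seed": seed})
    return result
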