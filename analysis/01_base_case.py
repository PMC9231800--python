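#!/usr/bin/env python
"""Base-case cost-effectiveness of durvalumab consolidation vs BSC.

Runs the deterministic three-state cohort model for both scenarios
(retail price, and with the Patient Assistance Program), prints the
discounted LY/QALY decomposition and the ICER, and writes the traces,
econ results, cost components and comparison under results/base_case*.

Cost totals rest on placeholder resource-use inputs (flagged in the run
manifest); the LY/QALY surface depends only on published inputs.
"""

from pathlib import Path

from durvacea.config import default_config
from durvacea.runner import run_base_case

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    for pap in (False, True):
        cfg = default_config(pap=pap)
        outdir = ROOT / "results" / ("base_case_pap" if pap else "base_case")
        res = run_base_case(cfg, outdir)
        label = "with PAP" if pap else "without PAP"
        print(f"\n== Base case {label} ==")
        for arm, e in res["econ"].items():
            print(
                f"  {arm:11s} LY {e.ly_total:5.2f} (PF {e.ly_pf:.2f} / PD {e.ly_pd:.2f})"
                f"  QALY {e.qaly_total:5.2f} (PF {e.qaly_pf:.2f} / PD {e.qaly_pd:.2f})"
            )
        c = res["comparison"]
        icer = f"{c.icer:,.2f} RMB/QALY" if c.icer is not None else c.label
        print(
            f"  dLY {c.delta_ly:.2f}  dQALY {c.delta_qaly:.2f}  "
            f"dCost {c.delta_cost:,.2f} RMB  ICER {icer}"
        )
        print(f"  cost-effective at WTP {c.wtp:,.0f}: {c.cost_effective}")
        print(f"  outputs -> {outdir}")


if __name__ == "__main__":
    main()
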