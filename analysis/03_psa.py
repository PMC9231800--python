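#!/usr/bin/env python
"""Probabilistic sensitivity analysis: 1,000 Monte-Carlo draws.

Samples every uncertain parameter from its assigned distribution (gamma
prices, beta utilities, uniform discount), re-evaluates the model per
draw, and writes the incremental cost/QALY cloud, the CEAC over a WTP
grid of 0-400,000 RMB, and a summary (ratio-of-means ICER, probability of
cost-effectiveness at the 212,676 RMB/QALY threshold).
"""

from pathlib import Path

from durvacea.config import default_config
from durvacea.runner import run_probabilistic

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = default_config()
    res = run_probabilistic(cfg, ROOT / "results" / "psa")
    print(f"PSA draws: {len(res.samples)} (failures: {len(res.failures)})")
    print(f"mean dCost {res.mean_delta_cost:,.2f} RMB")
    print(f"mean dQALY {res.mean_delta_qaly:.3f}")
    if res.icer is not None:
        print(f"ICER (ratio of means) {res.icer:,.2f} RMB/QALY")
    print(
        f"P(cost-effective at {res.wtp:,.0f} RMB/QALY) = {res.prob_cost_effective:.3f}"
    )


if __name__ == "__main__":
    main()
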