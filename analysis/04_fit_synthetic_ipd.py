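#!/usr/bin/env python
"""Fitting machinery exercised on synthetic IPD.

The patient-level trial data are unavailable, so this script simulates
right-censored TTP/PFS/PPS records from the published curves (2,000
patients per arm, 60-month administrative censoring), fits all six
parametric families per endpoint by censored maximum likelihood, and
tabulates AIC/BIC.  The generalized gamma is expected to win for TTP/PFS
and the log-normal to be competitive for PPS, matching the selection
reported for the real data.
"""

from pathlib import Path

import pandas as pd

from durvacea.config import default_config
from durvacea.simulate import SimConfig, simulate_ipd
from durvacea.survival import FAMILIES, fit_parametric, select_best

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = default_config()
    outdir = ROOT / "results" / "synthetic_fits"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for arm_name in ("durvalumab", "bsc"):
        arm = cfg.build_arm(arm_name)
        sim = SimConfig(
            n_patients=2000, ttp=arm.ttp, pfs=arm.pfs, pps=arm.pps,
            censor_time=60.0, seed=7,
        )
        records, _ = simulate_ipd(sim)
        for role, recs in records.items():
            fits = [fit_parametric(recs, fam) for fam in FAMILIES]
            best = select_best(fits, "aic")
            for f in fits:
                rows.append(
                    {
                        "arm": arm_name,
                        "endpoint": role,
                        "family": f.curve.family,
                        "params": [round(x, 4) for x in f.curve.params],
                        "loglik": round(f.loglik, 2),
                        "aic": round(f.aic, 2),
                        "bic": round(f.bic, 2),
                        "selected": f is best,
                    }
                )
            print(f"{arm_name:11s} {role}: best by AIC = {best.curve.family}")
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "fits.csv", index=False)
    print(f"\nfull table -> {outdir / 'fits.csv'}")


if __name__ == "__main__":
    main()
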