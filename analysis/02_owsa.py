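#!/usr/bin/env python
"""One-way sensitivity analysis (tornado) for the no-PAP scenario.

Each parameter moves to its 95% bounds with all others at base; rows are
sorted by ICER swing.  With the shipped configuration the durvalumab vial
prices dominate the cost side, mirroring the qualitative tornado of the
original analysis (whose resource-use inputs are placeholders here).
"""

from pathlib import Path

from durvacea.config import default_config
from durvacea.runner import run_owsa

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = default_config()
    table = run_owsa(cfg, ROOT / "results" / "owsa")
    print("Tornado (ICER swing, RMB/QALY):")
    print(table.to_string(index=False, float_format=lambda x: f"{x:,.1f}"))
    top = table.iloc[0].parameter
    print(f"\nLargest swing: {top}")


if __name__ == "__main__":
    main()
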