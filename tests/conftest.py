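import numpy as np
import pytest

from durvacea.cohort import ArmSpec, CycleGrid
from durvacea.survival import SurvivalCurve

# Published survival-curve rows (generalized gamma with the negated-shape
# convention for TTP/PFS; log-normal PPS shared by both arms).
PUBLISHED_CURVES = {
    "durvalumab": {
        "ttp": SurvivalCurve("gengamma", (0.6323, 0.6480, -7.3951)),
        "pfs": SurvivalCurve("gengamma", (0.6478, 0.6448, -6.9943)),
    },
    "bsc": {
        "ttp": SurvivalCurve("gengamma", (0.6384, 0.5739, -4.2698)),
        "pfs": SurvivalCurve("gengamma", (0.6274, 0.5416, -4.0697)),
    },
}
PPS = SurvivalCurve("lognormal", (3.0448, 1.1876))


@pytest.fixture(scope="session")
def grid():
    return CycleGrid.build()


@pytest.fixture(scope="session")
def short_grid():
    return CycleGrid.build(horizon_months=60.0)


def make_arm(name: str) -> ArmSpec:
    return ArmSpec(
        name=name,
        ttp=PUBLISHED_CURVES[name]["ttp"],
        pfs=PUBLISHED_CURVES[name]["pfs"],
        pps=PPS,
        utility_pf=0.901,
        utility_pd=0.863,
    )


@pytest.fixture(scope="session")
def durvalumab_arm():
    return make_arm("durvalumab")


@pytest.fixture(scope="session")
def bsc_arm():
    return make_arm("bsc")
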