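"""Individual-level microsimulation oracle for the cohort engine.

Applies the *identical* per-cycle update rules to a population of random
walkers: exit from PF with the PFS cycle probability, progression with the
TTP cycle probability (death = the floored difference), PD death from the
PPS curve on time since progression.  Life-years accrue exactly as in the
cohort engine (occupancy at cycle start times cycle length).  Used only as
a test oracle, never as a user-facing mode.
"""

from __future__ import annotations

import numpy as np

from durvacea.cohort import ArmSpec, CycleGrid
from durvacea.survival import survival

PF, PD, DEAD = 0, 1, 2


def microsimulate_ly(
    arm: ArmSpec, grid: CycleGrid, n_walkers: int, seed: int
) -> tuple[float, float]:
    """(mean undiscounted LY per walker, Monte-Carlo SE of that mean)."""
    rng = np.random.default_rng(seed)
    b = grid.array
    n = grid.n_cycles
    s_pfs = np.atleast_1d(survival(arm.pfs, b))
    s_ttp = np.atleast_1d(survival(arm.ttp, b))

    state = np.full(n_walkers, PF, dtype=np.int8)
    entry = np.zeros(n_walkers)  # PD entry boundary time
    ly = np.zeros(n_walkers)

    for i in range(n):
        t0, t1 = b[i], b[i + 1]
        dt_years = (t1 - t0) / 12.0
        alive = state != DEAD
        ly[alive] += dt_years  # occupancy valued at cycle start

        p_leave = 1.0 - s_pfs[i + 1] / s_pfs[i] if s_pfs[i] > 0 else 1.0
        p_prog = 1.0 - s_ttp[i + 1] / s_ttp[i] if s_ttp[i] > 0 else 1.0
        to_pd = min(p_prog, p_leave)

        in_pf = state == PF
        u = rng.uniform(size=n_walkers)
        progress = in_pf & (u < to_pd)
        die_pf = in_pf & (u >= to_pd) & (u < p_leave)
        state[progress] = PD
        entry[progress] = t1  # tunnel clock starts at the cycle boundary
        state[die_pf] = DEAD

        in_pd = (state == PD) & ~progress  # entrants are not at risk this cycle
        if np.any(in_pd):
            u0 = t0 - entry[in_pd]
            s0 = np.atleast_1d(survival(arm.pps, np.maximum(u0, 0.0)))
            s1 = np.atleast_1d(survival(arm.pps, np.maximum(u0, 0.0) + (t1 - t0)))
            q = 1.0 - np.where(s0 > 0, s1 / np.maximum(s0, 1e-300), 0.0)
            dies = rng.uniform(size=q.size) < q
            idx = np.flatnonzero(in_pd)[dies]
            state[idx] = DEAD

    return float(ly.mean()), float(ly.std(ddof=1) / np.sqrt(n_walkers))
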