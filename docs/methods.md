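# Methods

## Decision problem and model structure

The model compares consolidation durvalumab (10 mg/kg q2w, up to 12
months, stopped at progression) against best supportive care in
unresectable stage III NSCLC after chemoradiation. It is a cohort state
transition model with three states — progression-free (PF), progressed
disease (PD), death — evaluated on a cycle grid of 26 fourteen-day
cycles (≈ the first 12 months, one cycle per dosing interval) followed
by 28-day cycles to a 480-month horizon. 14-day and 28-day cycles
convert to months at 30.4375 days/month.

Three curves per arm drive the transitions. PFS governs *all* exits from
PF, TTP governs the PF→PD share, and PPS governs PD→death. Per cycle
`[t0, t1)`:

- `p_leave = 1 − S_PFS(t1)/S_PFS(t0)`
- `p_prog  = 1 − S_TTP(t1)/S_TTP(t0)` (capped at `p_leave`)
- `p_death_PF = p_leave − min(p_prog, p_leave)`

The cap keeps occupancy conserved if the TTP and PFS curves cross (they
do, by ≈1e−4, early on for the packaged durvalumab parameters). PD is a
tunnel: each cycle's progressors form a sub-cohort whose PPS clock
starts at the cycle boundary where they enter, and whose subsequent
survival ratios telescope, so the sub-cohort mass at boundary `t_i` is
`entrants_j · S_PPS(t_i − t_{j+1})`. Elapsed time is carried in months,
so the 14→28-day grid change needs no re-binning. A `pps_clock:
model_time` switch exists for falsification runs.

## Survival machinery

Six families: exponential, Weibull, log-normal, log-logistic, Gompertz
(negative shapes allowed, hence possibly defective), generalized gamma.
The generalized gamma uses the Prentice location/scale/signed-shape form
(see README); it nests the Weibull at Q = 1 exactly and the log-normal
as Q → 0 with first-order error `φ(0)/3·|Q|` (the gamma skewness term),
which the tests assert together with the convergence rate.

The published curve table prints positive shapes `k` with a
typographically garbled survival formula. The package maps `k → Q = −k`
by default: under that convention the implied medians (durvalumab PFS
≈ 32 months ≫ BSC ≈ 6.4 months; PPS median e^3.0448 ≈ 21 months) sit on
the trial's clinical scale, whereas `Q = +k` yields sub-week medians in
both arms. The sign is a config switch, not a hidden constant, and the
implementation was cross-checked value-for-value against
`flexsurv::pgengamma`.

Fitting maximizes the right-censored log-likelihood
`Σ [event·ln f(t) + (1−event)·ln S(t)]` with multi-start (5 seeded
starts) Nelder–Mead on log-transformed positive parameters; covariance
comes from the inverse observed information at the optimum (delta method
back to the natural scale) and may be absent if the curvature estimate
fails, which is reported rather than hidden. AIC/BIC selection breaks
exact ties by parameter count, then family order. Parameter recovery for
all six families (n = 2,000, 30% censoring, 3 SE) is part of the test
suite.

## Valuation

Occupancy is valued at cycle start for a full cycle length (no
half-cycle correction by default; full averaging is a switch, since the
original publication does not state its convention) and discounted at
the cycle midpoint by `(1+r)^(−t_mid/12)`, r = 0.05/year for both costs
and QALYs. Utilities: PF 0.901, PD 0.863 (published mixed-model
estimates). With a PSA draw where the PD utility exceeds PF the engine
warns but proceeds.

Drug cost per administration is an exact branch-and-bound over
non-negative integer vial counts (no sharing, wastage paid), verified
against brute-force enumeration. The PAP stages — 2 paid, 2 free, 4
paid, free thereafter until progression within the 12-month window —
are interpreted as q2w administrations, so a fully adherent
progression-free year costs 6 × 24,154 RMB instead of 26 × 24,154 RMB.
Other cost components (per-cycle PF/PD resource use, a
subsequent-treatment mix weighted into PD occupancy, one-off
incidence-weighted AE cost at entry, terminal care per incident death)
take config inputs; the original model's values came from an
unpublished expert survey, so the shipped numbers are placeholders
flagged in the run manifest and excluded from any reproduction claim.
Absolute cost totals and ICERs are therefore illustrative; the costing
*mechanics* are what the tests guarantee (component additivity, PAP
dominance, terminal cost = unit cost × cumulative deaths).

## Sensitivity analysis

OWSA moves each parameter to its 95% bounds (printed ranges where
available, otherwise ±1.96 SE) and sorts by ICER swing; perturbations
that push ΔQALY ≤ 0 are flagged, not dropped. PSA draws all uncertain
parameters independently — gamma for prices (moment-matched shape
`(m/se)²`, scale `se²/m`), beta for utilities (moment-matched), normal,
uniform for the discount rate (0–8%) — and re-evaluates the model per
draw. Survival-curve parameters are held fixed in the PSA (no published
sampling law for them; the state-occupancy traces are therefore
invariant across draws and are computed once). The summary ICER is the
ratio of mean increments; the CEAC reports the fraction of draws with
positive net monetary benefit over a WTP grid of 0–400,000 RMB in
2,000-RMB steps.

## Synthetic data

The patient-level trial data are unavailable, so the generator emulates
them: progression times from the TTP curve; pre-progression death from
the *excess* hazard `max(0, h_PFS − h_TTP)` (inverted from its
cumulative hazard on a fine grid), so the min structure reproduces the
PFS exit intensity and the generator is mutually consistent with the
engine's exit split; PPS drawn from the PPS curve for progressors;
administrative right-censoring. Utility observations arrive every 1.5
months while alive: state mean + patient random intercept
(SD 0.05) + residual (SD 0.05), clamped to the EQ-5D-5L-like range
[−0.5, 1]. The state-mean estimator is a random-intercept mixed model
(statsmodels MixedLM) with a closed-form fallback when the residual
variance is numerically zero.

What the generator does *not* emulate: covariate structure, visit
non-compliance, informative censoring, measurement floor/ceiling
clustering. Passing recovery tests therefore demonstrates internal
statistical consistency of the pipeline, not fidelity to the real trial
data.

Default generator conditions: 2,000 patients per arm (the scale at which
3-SE recovery is asserted), 60-month administrative censoring (roughly
the trial's follow-up order of magnitude), utility SDs 0.05/0.05 —
values chosen once as realistic for EQ-5D panel data and not tuned.

## Numerical choices

- Cycle probabilities come from survival ratios, never from rate
  approximations; occupancies must sum to 1 within 1e−10 every cycle or
  the engine aborts (no silent clamping).
- Inverse-CDF sampling for simulation uses a 4,000-point log-spaced grid
  of S(t) with enforced monotonicity; draws beyond 10⁶ months truncate
  (a guard for the very heavy generalized-gamma tails).
- Median survival uses bracketed Brent root-finding at 1e−10 relative
  tolerance; a curve that never reaches 0.5 reports infinity.
- Tornado ties and PSA draws are deterministic under a seed; base-case
  outputs are byte-identical across runs.

## Reproduction status of the published base case

The discounted LY/QALY cells of the published base-case table are *not*
reproducible from the published curve parameters under any convention
the package implements. The sweep (`analysis/05_convention_sweep.py`)
covers shape sign × half-cycle correction × PPS clock; the closest
configuration is the documented default, which lands the BSC arm ~4–7%
high and the durvalumab arm ~14–17% high (e.g. PF LY 7.00 vs 5.96
published). Because the PF cells depend only on `S_PFS`, the grid and
the discount rate — three fully specified ingredients — the residual gap
must lie in the published parameterization or in unpublished model
features. Two candidate explanations were tested quantitatively and
rejected: alternative generalized-gamma readings (log10, Stacy forms,
year/week time scales) move results by far more than the gap, and no
Gompertz background-mortality schedule can match both arms' PF cells
simultaneously. The durvalumab PFS curve's Pareto-like tail
(`S ~ t^{−1/(kσ)} = t^{−0.22}`, 27% progression-free at 40 years) makes
the discounted totals unusually sensitive to whatever tail handling the
original spreadsheet applied. The published QALY cells equal the LY
cells × the state utilities exactly, so they inherit the same gap.

## Known limitations

- No general-population background mortality: lifetime extrapolation
  rests entirely on the fitted curves, and the durvalumab tail is
  clinically implausible at the horizon.
- Independent PSA draws (no correlation structure, no survival-parameter
  uncertainty by default).
- Two-arm comparisons only; no efficiency frontier, no EVPI.
- Costing accuracy is bounded by the placeholder inputs; only the
  mechanics are validated.
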