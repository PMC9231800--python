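# Base-case scenario, durvalumab retail price (no Patient Assistance Program).
# Survival-curve rows, utilities, discount, WTP, vial prices, dosing and the
# PAP stages are published model inputs; every cost marked
# `source: placeholder` is an illustrative stand-in for expert-survey inputs
# that were never published, and is excluded from any reproduction claim.
scenario: base_case
pap: false
discount: 0.05
wtp: 212676.0
grid:
  first_cycle_days: 14.0
  later_cycle_days: 28.0
  phase_switch_months: 12.0
  horizon_months: 480.0
conventions:
  gengamma_sign: -1
  half_cycle_correction: false
  pps_clock: since_progression
utilities:
  pf: 0.901
  pd: 0.863
arms:
  durvalumab:
    ttp: {family: gengamma, params: [0.6323, 0.6480, 7.3951], source: published}
    pfs: {family: gengamma, params: [0.6478, 0.6448, 6.9943], source: published}
    pps: {family: lognormal, params: [3.0448, 1.1876], source: published}
  bsc:
    ttp: {family: gengamma, params: [0.6384, 0.5739, 4.2698], source: published}
    pfs: {family: gengamma, params: [0.6274, 0.5416, 4.0697], source: published}
    pps: {family: lognormal, params: [3.0448, 1.1876], source: published}
dose:
  dose_per_kg: 10.0
  body_weight: 61.2
  frequency_days: 14.0
  max_duration_months: 12.0
vials:
  - {size_mg: 120.0, price: 6066.0}
  - {size_mg: 500.0, price: 18088.0}
pap_schedule:
  stage1_paid: 2
  stage1_free: 2
  stage2_paid: 4
costs:
  durvalumab:
    resource_pf_per_cycle: {value: 450.0, source: placeholder}
    resource_pd_per_cycle: {value: 350.0, source: placeholder}
    subsequent_mix:
      - {label: chemotherapy, proportion: 0.40, cost_per_cycle: 2500.0, source: placeholder}
      - {label: targeted_therapy, proportion: 0.30, cost_per_cycle: 5000.0, source: placeholder}
      - {label: immunotherapy, proportion: 0.30, cost_per_cycle: 16000.0, source: placeholder}
    ae_cost_onceoff: {value: 0.0, source: placeholder}
    terminal_care_cost: {value: 20000.0, source: placeholder}
  bsc:
    resource_pf_per_cycle: {value: 450.0, source: placeholder}
    resource_pd_per_cycle: {value: 350.0, source: placeholder}
    subsequent_mix:
      - {label: chemotherapy, proportion: 0.30, cost_per_cycle: 2500.0, source: placeholder}
      - {label: targeted_therapy, proportion: 0.25, cost_per_cycle: 5000.0, source: placeholder}
      - {label: immunotherapy, proportion: 0.45, cost_per_cycle: 16000.0, source: placeholder}
    ae_cost_onceoff: {value: 0.0, source: placeholder}
    terminal_care_cost: {value: 20000.0, source: placeholder}
params:
  - {name: durvalumab_120_price, base: 6066.0, se: 606.60, low: 4935.54, high: 7311.29, distribution: gamma}
  - {name: durvalumab_500_price, base: 18088.0, se: 1808.80, low: 14717.12, high: 21801.28, distribution: gamma}
  - {name: utility_pf, base: 0.901, se: 0.009, low: 0.883, high: 0.918, distribution: beta}
  - {name: utility_pd, base: 0.863, se: 0.009, low: 0.845, high: 0.880, distribution: beta}
  - {name: discount_rate, base: 0.05, se: 0.0, low: 0.0, high: 0.08, distribution: uniform}
  - {name: terminal_care_cost, base: 20000.0, se: 2000.0, distribution: gamma}
  - {name: resource_pf_per_cycle, base: 450.0, se: 45.0, distribution: gamma}
  - {name: resource_pd_per_cycle, base: 350.0, se: 35.0, distribution: gamma}
psa:
  n: 1000
  seed: 1
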