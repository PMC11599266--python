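# Default decision-model parameters: trifluridine/tipiracil + bevacizumab
# vs. trifluridine/tipiracil monotherapy, Chinese healthcare-system
# perspective (costs in 2023 CNY, survival times in months).
schema_version: 1
model:
  cycle_days: 28
  horizon_years: 10
  annual_discount: 0.05
  wtp: 268200.00
  half_cycle_correction: false
  transition_mode: markov
strategies:
  - name: "FTD/TPI plus bevacizumab"
    key: combo
    role: intervention
    drug_cost_per_cycle: 23625.40
    os_model: {family: lognormal, shape: 2.398, scale: 0.808}
    pfs_model: {family: lognormal, shape: 1.660, scale: 0.850}
    adverse_events:
      - {name: neutropenia, incidence: 0.431, unit_cost: 3214.90}
      - {name: nausea, incidence: 0.016, unit_cost: 298.00}
      - {name: anemia, incidence: 0.061, unit_cost: 531.00}
      - {name: fatigue, incidence: 0.041, unit_cost: 20.80}
      - {name: tiredness, incidence: 0.012, unit_cost: 293.01}
      - {name: diarrhea, incidence: 0.008, unit_cost: 276.00}
      - {name: decreased_appetite, incidence: 0.008, unit_cost: 705.40}
  - name: "FTD/TPI"
    key: mono
    role: comparator
    drug_cost_per_cycle: 13947.40
    os_model: {family: lognormal, shape: 2.030, scale: 0.793}
    pfs_model: {family: lognormal, shape: 1.110, scale: 0.644}
    adverse_events:
      - {name: neutropenia, incidence: 0.321, unit_cost: 3214.90}
      - {name: nausea, incidence: 0.016, unit_cost: 298.00}
      - {name: anemia, incidence: 0.110, unit_cost: 531.00}
      - {name: fatigue, incidence: 0.041, unit_cost: 20.80}
costs:
  lab_per_visit: 317.36
  imaging_per_visit: 677.70
  supportive_per_cycle: 2141.20
  end_of_life_once: 11299.00
  subsequent_tx_per_cycle: 7541.10
utilities:
  u_pfs: 0.84
  u_pd: 0.57
sensitivity:
  n_sims: 10000
  parameters:
    - {name: drug_cost.combo, baseline: 23625.40, low: 18900.32, high: 28350.48, distribution: gamma}
    - {name: drug_cost.mono, baseline: 13947.40, low: 11157.92, high: 16736.88, distribution: gamma}
    - {name: cost.lab_per_visit, baseline: 317.36, low: 253.89, high: 380.83, distribution: gamma}
    - {name: cost.imaging_per_visit, baseline: 677.70, low: 542.16, high: 813.24, distribution: gamma}
    - {name: cost.end_of_life_once, baseline: 11299.00, low: 9039.20, high: 13558.80, distribution: gamma}
    - {name: cost.supportive_per_cycle, baseline: 2141.20, low: 1712.96, high: 2569.44, distribution: gamma}
    # source table prints the upper limit as "9.49.32"; read as 9049.32 (= 1.2 x baseline)
    - {name: cost.subsequent_tx_per_cycle, baseline: 7541.10, low: 6032.88, high: 9049.32, distribution: gamma}
    - {name: ae_cost.neutropenia, baseline: 3214.90, low: 2571.92, high: 3857.88, distribution: gamma}
    - {name: ae_cost.nausea, baseline: 298.00, low: 238.40, high: 357.60, distribution: gamma}
    - {name: ae_cost.anemia, baseline: 531.00, low: 424.80, high: 637.20, distribution: gamma}
    - {name: ae_cost.fatigue, baseline: 20.80, low: 16.64, high: 24.96, distribution: gamma}
    - {name: ae_cost.tiredness, baseline: 293.01, low: 234.41, high: 351.61, distribution: gamma}
    - {name: ae_cost.diarrhea, baseline: 276.00, low: 220.80, high: 331.20, distribution: gamma}
    - {name: ae_cost.decreased_appetite, baseline: 705.40, low: 564.32, high: 846.48, distribution: gamma}
    - {name: utility.pfs, baseline: 0.84, low: 0.67, high: 1.00, distribution: beta, support: [0.0, 1.0]}
    - {name: utility.pd, baseline: 0.57, low: 0.46, high: 0.68, distribution: beta, support: [0.0, 1.0]}
    - {name: discount_rate, baseline: 0.05, low: 0.00, high: 0.08, distribution: beta, support: [0.0, 0.08]}
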