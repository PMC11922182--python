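# Base-case inputs: published event rates and unit costs (2022 USD) for the
# wearable heart-failure management system (HFMS) vs standard of care (SOC),
# plus the run settings and structural assumptions documented in
# docs/methods.md. Cumulative probabilities are stated over `period_days`;
# "early" rates cover the first 90 days after discharge, "late" rates the
# remainder of year 1 (days 91-365).
rates:
  hosp_early: {mean: 0.3255, ci: [0.2403, 0.4163], period_days: 90}
  hosp_late: {mean: 0.5221, ci: [0.3928, 0.6499], period_days: 275}
  er_early: {mean: 0.1383, ci: [0.0821, 0.2049], period_days: 90}
  er_late: {mean: 0.500, ci: [0.2993, 0.7007], period_days: 275}
  mort_early: {mean: 0.0346, ci: [0.0212, 0.0506], period_days: 90}
  mort_late: {mean: 0.0913, ci: [0.0649, 0.1214], period_days: 275}
effects:
  hr_hosp: {mean: 0.62}                       # hazard ratio, readmission, days 1-90
  rr_mort: {mean: 0.66, ci: [0.24, 1.82]}     # risk ratio, mortality, days 1-90
costs:
  device_monthly: {mean: 1300.0, unit: per_month, sample_in_psa: false}
  outpatient_daily: {mean: 50.0, unit: per_day, ci: [35.0, 65.0]}
  er_visit: {mean: 997.0, unit: per_visit, ci: [482.0, 1458.0]}
  hospital_daily: {mean: 2665.0, unit: per_day, ci: [2572.0, 4828.0]}
  icu_daily: {mean: 3417.0, unit: per_day, ci: [2392.0, 4442.0]}
  post_readmission_outpatient: {mean: 236.0, unit: per_day, ci: [212.0, 259.0]}
settings:
  horizon_days: 1825
  cycle_days: 1
  discount_rate_annual: 0.03
  wtp_per_readmission_avoided: 10737.0
  wtp_alternative: 17830.0
  effect_window_days: 90
  eoc_fraction: 0.025
  device_wear_months: 2
  psa_iterations: 1000
  owsa_fraction: 0.10
  # Billed length of stay per readmission; calibrated against the two 90-day
  # per-arm discounted cost totals (least squares; `hfcea calibrate`).
  hospital_los_days: 6.87
  hospital_hold_days: 1
  eoc_los_days: 5.0
  eoc_hold_days: 1
  er_to_hosp_fraction: 0.0
  late_window_days: 275
  post_readmission_additive: false
  seed: 20220101
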