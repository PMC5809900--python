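# One-year screening interval (multivariate sensitivity analysis).
# Incidences are one-year probabilities; treatment costs re-estimated for annual cycles.
scenario: cycle_1y
shared:
  xray_sensitivity: 1.0
  xray_specificity: 1.0
  vfa_sensitivity: 0.82
  vfa_specificity: 0.93
  p_vfa_unreadable: 0.03
  cost_vfa: 17.0
  cost_xray: 24.0
  cost_physician_visit: 9.0
  dose_xray: 600.0
  dose_vfa: 25.0
  discount_rate: 0.05
  cycle_length: 1.0
  horizon: 10.0
  asymptomatic_ratio: 2.8
  cohort_size: 1000
female:
  vf_prevalence: 0.22
  vf_incidence: 0.06
  new_vf_incidence: 0.11
  rr_treatment: 0.58
  cost_vf_treatment: 1458.0
  cost_drug_year: 180.0
  cost_procedure: 809.0
  population_weight: 8649974
male:
  vf_prevalence: 0.11
  vf_incidence: 0.02
  new_vf_incidence: 0.11
  rr_treatment: 0.38
  cost_vf_treatment: 1509.0
  cost_drug_year: 194.0
  cost_procedure: 934.0
  population_weight: 7590057
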