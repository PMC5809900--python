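# Base-case inputs: population aged >= 50, two-year screening cycle, 10-year horizon.
# All monetary values are 2013 euros; doses are microsievert per performed test.
scenario: base_case
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
  cycle_length: 2.0
  horizon: 10.0
  asymptomatic_ratio: 2.8
  cohort_size: 1000
female:
  vf_prevalence: 0.22
  vf_incidence: 0.12
  new_vf_incidence: 0.22
  rr_treatment: 0.58
  cost_vf_treatment: 1526.0
  cost_drug_year: 180.0
  cost_procedure: 809.0
  population_weight: 8649974
male:
  vf_prevalence: 0.11
  vf_incidence: 0.05
  new_vf_incidence: 0.22
  rr_treatment: 0.38
  cost_vf_treatment: 1707.0
  cost_drug_year: 194.0
  cost_procedure: 934.0
  population_weight: 7590057
# Bracketed one-way sensitivity values; each entry defines one univariate variant.
univariate:
  female:
    vf_prevalence: 0.08
    vf_incidence: 0.13
    new_vf_incidence: 0.23
    rr_treatment: 0.64
    vfa_sensitivity: 0.74
    vfa_specificity: 0.89
    p_vfa_unreadable: 0.05
    cost_vfa: 40.0
    cost_xray: 17.0
    cost_vf_treatment: 1249.0
    dose_vfa: 2.0
  male:
    vf_prevalence: 0.03
    vf_incidence: 0.05
    new_vf_incidence: 0.23
    rr_treatment: 0.41
    vfa_sensitivity: 0.74
    vfa_specificity: 0.89
    p_vfa_unreadable: 0.05
    cost_vfa: 40.0
    cost_xray: 17.0
    cost_vf_treatment: 1336.0
    dose_vfa: 2.0
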