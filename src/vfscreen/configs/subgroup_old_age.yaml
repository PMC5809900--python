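# Old-age subgroup: women aged 70+ and men aged 80+ (guideline-recommended VFA groups).
# Higher prevalence/incidence, elderly-specific VFA accuracy, pooled RR 0.60.
scenario: subgroup_old_age
shared:
  xray_sensitivity: 1.0
  xray_specificity: 1.0
  vfa_sensitivity: 0.88
  vfa_specificity: 0.99
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
  vf_prevalence: 0.43
  vf_incidence: 0.29
  new_vf_incidence: 0.32
  rr_treatment: 0.60
  cost_vf_treatment: 1513.0
  cost_drug_year: 180.0
  cost_procedure: 809.0
  population_weight: 8649974
male:
  vf_prevalence: 0.46
  vf_incidence: 0.17
  new_vf_incidence: 0.32
  rr_treatment: 0.60
  cost_vf_treatment: 1675.0
  cost_drug_year: 194.0
  cost_procedure: 934.0
  population_weight: 7590057
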