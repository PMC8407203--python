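regime: regime2017
score_model: norrisk2
hypertension_mode: standard
score_thresholds:
  45-54: 5.0
  55-64: 10.0
  65-74: 15.0
medium_thresholds:
  45-54: 2.5
  55-64: 5.0
  65-74: 7.5
criteria:
- id: total_chol_ge_7
  field: total_chol
  cutoff: 7.0
  exempt_women_from_age: 50.0
- id: ldl_ge_5
  field: ldl_chol
  cutoff: 5.0
  exempt_women_from_age: 50.0
- id: sbp_ge_160
  field: sbp
  cutoff: 160.0
  international_cutoff: 140.0
- id: dbp_ge_100
  field: dbp
  cutoff: 100.0
  international_cutoff: 90.0
- id: diabetes_ldl_ge_2_5
  field: ldl_chol
  cutoff: 2.5
  requires_diabetes: true
- id: diabetes_bp_ge_140_90
  sbp_cutoff: 140.0
  dbp_cutoff: 90.0
  requires_diabetes: true
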