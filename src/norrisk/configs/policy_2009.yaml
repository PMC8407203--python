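regime: regime2009
score_model: norrisk1
hypertension_mode: standard
score_thresholds:
  40-49: 1.0
  50-59: 5.0
  60-69: 10.0
medium_thresholds: null
criteria:
- id: total_chol_ge_8
  field: total_chol
  cutoff: 8.0
- id: sbp_ge_160
  field: sbp
  cutoff: 160.0
  international_cutoff: 140.0
- id: dbp_ge_100
  field: dbp
  cutoff: 100.0
  international_cutoff: 90.0
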