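# NORRISK 2 coefficient configuration -- SYNTHETIC CALIBRATION.
#
# NORRISK 2 predicts 10-year risk (%) of incident myocardial infarction
# and stroke combined (fatal + non-fatal) from age, sex, systolic blood
# pressure, total cholesterol, daily smoking, family history of
# premature MI (before age 60), low HDL cholesterol at sex-specific
# cut-offs (< 1.0 mmol/L men, < 1.3 mmol/L women) and current
# antihypertensive use (use increases the score). The optional South
# Asian ethnicity / rheumatoid arthritis multipliers are intentionally
# absent (not used in the comparison this package implements).
#
# The numeric values below are package-authored stand-ins chosen for
# epidemiologically plausible magnitudes; they are NOT the published
# model coefficients.
model_id: norrisk2
version: synthetic-2017.1
description: >-
  Synthetic calibration of the NORRISK 2 functional form (Cox-family risk
  equation, per-sex baseline survival). Values are plausible stand-ins,
  not the published coefficients.
sex:
  woman:
    coefficients:
      age: 0.09
      sbp: 0.18
      total_chol: 0.20
      smoking: 0.80
      low_hdl: 0.35
      family_history_mi: 0.45
      antihypertensive_use: 0.25
    transforms:
      age: {field: age, type: linear, center: 55.0, scale: 1.0}
      sbp: {field: sbp, type: linear, center: 130.0, scale: 10.0}
      total_chol: {field: total_chol, type: linear, center: 6.0, scale: 1.0}
      smoking: {field: smoking, type: indicator}
      low_hdl: {field: hdl_chol, type: below, cutoff: 1.3}
      family_history_mi: {field: family_history_mi, type: indicator}
      antihypertensive_use: {field: antihypertensive_use, type: indicator}
    baseline_survival: 0.985
    lp_ref: 0.0
  man:
    coefficients:
      age: 0.06
      sbp: 0.18
      total_chol: 0.20
      smoking: 0.60
      low_hdl: 0.35
      family_history_mi: 0.45
      antihypertensive_use: 0.25
    transforms:
      age: {field: age, type: linear, center: 55.0, scale: 1.0}
      sbp: {field: sbp, type: linear, center: 130.0, scale: 10.0}
      total_chol: {field: total_chol, type: linear, center: 6.0, scale: 1.0}
      smoking: {field: smoking, type: indicator}
      low_hdl: {field: hdl_chol, type: below, cutoff: 1.0}
      family_history_mi: {field: family_history_mi, type: indicator}
      antihypertensive_use: {field: antihypertensive_use, type: indicator}
    baseline_survival: 0.960
    lp_ref: 0.0
multipliers: []
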