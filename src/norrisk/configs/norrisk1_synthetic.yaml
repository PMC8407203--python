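# NORRISK 1 coefficient configuration -- SYNTHETIC CALIBRATION.
#
# NORRISK 1 predicts 10-year risk (%) of fatal atherosclerotic CVD in
# ages 40-69 from age, sex, systolic blood pressure, serum total
# cholesterol and daily smoking, with multiplicative recalculation for
# elevated HbA1c and family history of premature coronary heart disease.
#
# The numeric values below are package-authored stand-ins chosen for
# epidemiologically plausible magnitudes; they are NOT the published
# model coefficients. Swap in a transcription of the published values to
# reproduce the clinical score exactly.
model_id: norrisk1
version: synthetic-2009.1
description: >-
  Synthetic calibration of the NORRISK 1 functional form (Cox-family risk
  equation, per-sex baseline survival). Values are plausible stand-ins,
  not the published coefficients.
sex:
  woman:
    coefficients:
      age: 0.12          # per year
      sbp: 0.26          # per 10 mm Hg
      total_chol: 0.28   # per mmol/L
      smoking: 0.85      # current daily smoker
    transforms:
      age: {field: age, type: linear, center: 55.0, scale: 1.0}
      sbp: {field: sbp, type: linear, center: 130.0, scale: 10.0}
      total_chol: {field: total_chol, type: linear, center: 6.0, scale: 1.0}
      smoking: {field: smoking, type: indicator}
    baseline_survival: 0.993
    lp_ref: 0.0
  man:
    coefficients:
      age: 0.10
      sbp: 0.27
      total_chol: 0.30
      smoking: 0.70
    transforms:
      age: {field: age, type: linear, center: 55.0, scale: 1.0}
      sbp: {field: sbp, type: linear, center: 130.0, scale: 10.0}
      total_chol: {field: total_chol, type: linear, center: 6.0, scale: 1.0}
      smoking: {field: smoking, type: indicator}
    baseline_survival: 0.982
    lp_ref: 0.0
# Additional-factor recalculation (2009-guideline style): multiplicative
# factors on the risk percentage with configurable condition cut-offs.
multipliers:
  - id: hba1c_elevated
    field: hba1c
    op: ge
    value: 6.0
    factor: 1.5
  - id: family_history_premature_chd
    field: family_history_chd
    op: is_true
    value: null
    factor: 1.5
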