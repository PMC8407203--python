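# norrisk

Cardiovascular-disease (CVD) primary-prevention guidelines identify who
should be offered lifestyle advice or drug treatment by combining a
multivariable 10-year risk score with single-risk-factor cut-offs.
When a country replaces both the score and the guideline — as Norway did
in 2017, moving from NORRISK 1 (10-year risk of fatal CVD) with the 2009
guidelines to NORRISK 2 (10-year risk of fatal *and* non-fatal
myocardial infarction and stroke) with the 2017 guidelines — the
population proportion "eligible for intervention" changes, with direct
consequences for workload and treatment burden.

`norrisk` is a tested pipeline for quantifying that change. It is aimed
at epidemiologists and health-services researchers who want to run
regime comparisons on their own cohort data, or to study the behaviour
of threshold-based eligibility rules on simulated populations. It
provides:

* **Risk-score engines** for NORRISK 1 and NORRISK 2. Both are
  Cox-family risk equations

  `risk% = 100 · (1 − S₀^exp(lp − lp_ref))`, with
  `lp = Σⱼ βⱼ · tⱼ(xⱼ)`,

  driven entirely by versioned coefficient configuration (per-sex β,
  predictor transforms, baseline survival S₀, multiplicative
  additional-factor recalculation for elevated HbA1c and family
  history). The shipped configs are clearly-labelled **synthetic
  calibrations** — the published coefficient values are not
  redistributed here — so swap in your own transcription to reproduce
  the clinical scores exactly.
* **Guideline rule engines** for the 2009 regime (total cholesterol
  ≥ 8 mmol/L, SBP ≥ 160 or DBP ≥ 100 mm Hg; NORRISK 1 thresholds
  1/5/10 % for ages 40–49/50–59/60–69) and the 2017 regime (total
  cholesterol ≥ 7 and LDL ≥ 5 mmol/L — neither applying to women aged
  50+ — SBP ≥ 160, DBP ≥ 100, and diabetes-specific LDL ≥ 2.5 mmol/L or
  BP ≥ 140/90; NORRISK 2 thresholds by ages 45–54/55–64/65–74), plus an
  "international" sensitivity mode that lowers the plain BP cut-offs to
  140/90 mm Hg.
* **A seeded synthetic cohort generator** (Gaussian copula) calibrated
  to published sex × age-band marginal distributions of a Norwegian
  general population aged 40–69, so the full pipeline is runnable and
  testable without access to restricted survey data.
* **The comparison pipeline**: exclusion flow with stage tallies,
  stratified eligibility tables, percentage-point deltas (on reported
  and unrounded scales), Venn overlap partitions, McNemar paired tests
  and between-sex t/χ² tests.

## Worked example

```python
from norrisk import (default_tromso_spec, generate_cohort, classify_cohort,
                     build_eligibility_table, venn_partition, mcnemar_test,
                     percentage_point_delta)

cohort = generate_cohort(default_tromso_spec(16_566, seed=1))
t2009 = build_eligibility_table(cohort, "regime2009")
t2017 = build_eligibility_table(cohort, "regime2017")
r2009 = classify_cohort(cohort, "regime2009")
r2017 = classify_cohort(cohort, "regime2017")

for regime, t in (("2009", t2009), ("2017", t2017)):
    print(f"{regime}: score high {t.percent('score_high'):4.1f}%  "
          f"total eligible {t.percent('total_eligible'):4.1f}%  "
          f"(women {t.percent('total_eligible', 'woman'):4.1f}%, "
          f"men {t.percent('total_eligible', 'man'):4.1f}%)")

delta = percentage_point_delta(t2009, t2017)
print(f"2017 minus 2009 total: {delta.delta_reported:+.1f} percentage points")

venn = venn_partition([r.eligible for r in r2009],
                      [r.eligible for r in r2017], "2009", "2017")
print(f"overlap: both {venn.both}, only 2009 {venn.only_a}, "
      f"only 2017 {venn.only_b}, neither {venn.neither}")
test = mcnemar_test([r.eligible for r in r2009], [r.eligible for r in r2017])
print(f"McNemar chi2 = {test.statistic:.1f}, p = {test.p_value:.2e}")
```

prints

```
2009: score high 13.2%  total eligible 15.5%  (women  6.0%, men 26.5%)
2017: score high  8.9%  total eligible 17.5%  (women  8.3%, men 28.3%)
2017 minus 2009 total: +2.0 percentage points
overlap: both 1562, only 2009 1003, only 2017 1344, neither 12657
McNemar chi2 = 49.5, p = 1.94e-12
```

Read: on this synthetic 16 566-person cohort, 13.2 % are high-risk by
NORRISK 1 score versus 8.9 % by NORRISK 2 (the scores predict different
endpoints, so the score-only proportions are not directly comparable),
but once single-risk-factor criteria are added the 2017 regime makes
*more* people eligible (17.5 % vs 15.5 %, +2.0 percentage points) — the
lowered total-cholesterol cut-off and the new LDL cut-off dominate. The
Venn partition shows the two regimes agree on 1 562 eligible and 12 657
non-eligible people; the McNemar test on the 2 347 discordant pairs
rejects marginal homogeneity.

The same workflow is available from the shell:

```sh
norrisk simulate --n 16566 --seed 1 --out cohort.csv
norrisk compare --cohort cohort.csv --out reports/
norrisk compare --cohort cohort.csv --hypertension-mode international --out reports_intl/
```

## Layout

| module | contents |
| --- | --- |
| `norrisk.cohort` | participant data model, BP averaging, age bands, validation, exclusion flow, CSV schema |
| `norrisk.engines` | NORRISK 1/2 score engines and coefficient-config loader |
| `norrisk.rules` | 2009/2017 threshold policies and eligibility decisions |
| `norrisk.simulate` | Gaussian-copula synthetic cohort generator |
| `norrisk.compare` | tables, deltas, Venn partitions, statistical tests |
| `norrisk.cli` | `norrisk` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter
provenance and known limitations.
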