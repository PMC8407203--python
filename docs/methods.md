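# Methods

## The two regimes

Both risk scores are evaluated as Cox-family risk equations,

    risk% = 100 · (1 − S₀^exp(lp − lp_ref)),   lp = Σⱼ βⱼ · tⱼ(xⱼ),

with per-sex coefficients, predictor transforms, 10-year baseline
survival S₀ and a centering constant lp_ref held in versioned YAML
configuration. The engine code contains no clinical constants at all:
an all-zero-coefficient config provably returns 100·(1 − S₀) for every
profile, which the test suite asserts.

**NORRISK 1** (10-year fatal CVD risk, ages 40–69) uses age, systolic
blood pressure, total cholesterol and daily smoking. The 2009-guideline
"additional risk factors" — elevated HbA1c and a first-degree family
history of premature coronary heart disease — are implemented as
multiplicative factors on the risk percentage with configurable
condition cut-offs (defaults: HbA1c ≥ 6.0 % → ×1.5, family history →
×1.5). Multiplicative recalculation is the simplest auditable reading of
"recalculate risk with specific cut-offs", and because every factor is
≥ 1, switching them off can only lower scores — a property the tests
check per individual. The off mode mirrors the sensitivity analysis
without additional factors.

**NORRISK 2** (10-year fatal + non-fatal MI/stroke risk) adds a low-HDL
indicator at sex-specific cut-offs (< 1.0 mmol/L men, < 1.3 mmol/L
women), family history of premature MI (before age 60) and current
antihypertensive use, whose coefficient is positive (treated
hypertension marks residual risk). The optional South Asian ethnicity
and rheumatoid-arthritis multipliers are deliberately not part of the
default config: the comparison this package implements does not use
them.

**Eligibility** under a regime is the disjunction of (a) score at or
above the age-band threshold — 1/5/10 % for 40–49/50–59/60–69 under
2009; 5/10/15 % for 45–54/55–64/65–74 under 2017 — and (b) any
single-risk-factor criterion. All comparisons are closed (≥). The
2017 cholesterol criteria (total ≥ 7, LDL ≥ 5 mmol/L) do not apply to
women aged 50 or over; the exemption is implemented as `age ≥ 50`,
matching the table convention that the whole 50–59 stratum is exempt
(the phrase "over 50 years" is ambiguous for a woman aged exactly 50;
the choice matters only for fractional ages in [50, 51)). "Blood
pressure ≥ 140/90" is parsed disjunctively, SBP ≥ 140 **or** DBP ≥ 90,
the standard hypertension-definition convention. The *international*
hypertension mode replaces the plain BP cut-offs 160/100 by 140/90
mm Hg and leaves everything else unchanged, so eligibility under it is
a superset of the standard mode — property-tested.

NORRISK 2 also carries a low/medium/high score class (medium starting
at half the high threshold by default); only the high class affects
eligibility, the medium class is reported for downstream use. Ages
40–44 are scored with NORRISK 2 but its thresholds start at 45, so they
are assigned the lowest band with an explicit `below_band` flag rather
than a silently invented band.

### Coefficient provenance

The published NORRISK coefficient values are not redistributed in this
package. The shipped configs (`configs/norrisk1_synthetic.yaml`,
`configs/norrisk2_synthetic.yaml`) are **synthetic calibrations**: the
functional form, predictor sets, transform structure and cut-offs follow
the published model descriptions, while the numeric β/S₀ values are
package-authored stand-ins chosen for epidemiologically plausible
magnitudes (hazard-ratio scale ≈ 1.06–1.13 per year of age, ≈ 1.2–1.3
per 10 mm Hg SBP or mmol/L cholesterol, ≈ 1.8–2.3 for smoking) and
moment-matched so that the synthetic-cohort stratified high-risk
proportions fall in the published range. Every test that asserts an
exact numeric score uses a frozen test config instead of these
defaults, so replacing them with a transcription of the published
values changes no test.

## Preprocessing and exclusions

Blood pressure is measured three times seated; the analysis value is
the mean of the final two readings, discarding the first. With only two
readings the mean of both is used, with one that reading itself — both
fallbacks carry a `degraded` quality flag, since the source protocol
does not specify the partial-set rule and this is a documented package
choice.

The exclusion flow runs in a fixed order so stage tallies are well
defined: age ≥ 70 first, then prior MI/stroke, then records failing
validation for either regime's score computation; a record is counted
only at the first stage it fails. Validation checks presence of every
field the regime needs plus plausibility bounds (defaults: SBP 60–260,
DBP 30–160 mm Hg, total cholesterol 1.5–16, LDL 0.3–12, HDL 0.3–5
mmol/L, HbA1c 2.5–20 %, age 20–110 y), SBP > DBP, and lipid consistency
LDL + HDL ≤ total + 0.3 mmol/L (with a 10⁻⁹ float guard). Missing
values are explicit — `None` in memory, the empty field in CSV — never
zero, because 0 is a valid-looking but clinically impossible value.

## The synthetic cohort generator

The generator emulates the sex × age-band structure of a Norwegian
general-population survey of 16 566 participants aged 40–69: six strata
sized proportionally to the published counts (3286/3115/2495 women,
2943/2579/2148 men by decade), each with published means/SDs for
total/LDL/HDL cholesterol, systolic/diastolic BP and HbA1c, and
published prevalences for smoking, diabetes and antihypertensive /
lipid-lowering drug use.

Joints use a Gaussian copula: one latent multivariate normal per
stratum over 7 continuous + 6 binary-latent variables. Continuous
margins are affine maps of their latent normals, truncated to the
plausibility bounds by rejection; binary margins dichotomize their
latent at the quantile matching the target prevalence (probit link), so
smoking or diabetes can be made to correlate with continuous factors
when configured. Ages are uniform within each band. Rows violating
SBP > DBP or lipid consistency are redrawn. Default correlations —
total–LDL 0.9, SBP–DBP 0.7, total–HDL 0.1, age–SBP 0.25, all others
0 — are modelling choices, not published values: margins alone do not
determine joint-criterion proportions, so the correlation matrix is
explicit, per-stratum and swappable. Family-history prevalences (MI
0.10, CHD 0.15) are likewise placeholders with no published source;
no reported quantity depends on them numerically.

What passing tests on these cohorts do **not** show: agreement with the
real survey's joint tail behaviour (real risk factors are skewed and
heteroscedastic; a Gaussian copula with linear margins is symmetric),
measurement error, item non-response patterns, or the published Table-2
proportions themselves, which depend on the real coefficients and the
real joint distribution. The synthetic comparison reproduces the
*structure* and *direction* of the published results (2017 regime
eligibility exceeds 2009; the cholesterol rules drive the increase),
not their exact values.

### Moment-recovery tolerances

Rejection steps bias the realised margins, so the recovery checks use
an analytic tolerance rather than pure sampling noise:
3·sd/√n plus two documented bias bounds, each evaluated from the spec
alone (no data):

* bound truncation — one-sided Gaussian truncation at standardized
  distance *a* shifts a mean by at most sd·φ(a)/Φ(a) per side;
* lipid-consistency resampling — the acceptance region is approximated
  by the half-space D = LDL + HDL − total − 0.3 ≤ 0; conditioning a
  jointly normal X on it shifts E[X] by corr(X, D)·sd_X·φ(z)/Φ(z) at
  the standardized cut z.

Both bounds are doubled to absorb the Gaussian-approximation error of
treating the joint acceptance region as a single half-space; the factor
was fixed before the checks were first run. At the default calibration
the lipid bound is ≈ 0.05–0.1 mmol/L for the cholesterol fractions and
zero elsewhere. Binary margins are unaffected by the default
configuration (zero correlation between binary latents and the lipids),
so prevalences are checked at 3 binomial standard errors exactly.

Note one self-limitation of the copula-sanity invariant: under an
identity correlation matrix the lipid-consistency constraint itself
induces correlation among the three cholesterol fractions (the
acceptance region is not a product set). Constraint enforcement is
therefore a generator flag; the sanity check runs on unconstrained
pairs with enforcement on, and on all pairs with it off.

## Reporting conventions

Percentages are rounded half-up to one decimal, as printed tables do;
all internal arithmetic is unrounded, and percentage-point deltas are
returned on **both** scales, labelled `delta_reported` (difference of
rounded percents, itself re-rounded) and `delta_unrounded`. Table
criterion rows count individuals who are *not* score-high and trigger
that criterion; rows are not mutually exclusive and the total-eligible
row counts the union once — the only reading under which rows can sum
to more than the total without contradiction. The decomposition
`eligible = score_high + single_factor_only` is exact and
property-tested, as is consistency between table totals and Venn region
counts.

McNemar's test uses the uncorrected statistic (b − c)²/(b + c) on one
degree of freedom, switching to the exact two-sided binomial tail of
Bin(b + c, ½) when b + c < 25, and returning statistic 0, p = 1 when
there are no discordant pairs. Between-sex comparisons use Welch's
unequal-variance t (the safer default where equal variances were not
asserted) and Pearson's χ² without continuity correction; both choices
are configurable at the call site in the statistical sense that the
raw counts are returned alongside.

## Problem sizes

The shipped regression fixture is a frozen synthetic cohort of n = 500
(`data/validation_cohort_synthetic.csv`, seed 2021). Moment recovery is
checked at n = 50 000 (≈ 9 000–11 000 per stratum), conservation
properties across 100 seeds at n = 120 each, and the acceptance script
generates its comparison cohort at the full analysis size n = 16 566 —
sizes chosen so the whole suite runs in well under a minute on one CPU
while keeping binomial standard errors small relative to the quantities
checked.

## Known limitations

* The default engine configs are stand-ins (above); absolute synthetic
  proportions shift if the published coefficients are substituted.
* The generator draws family history independently of lipids and BP by
  default, which understates familial clustering of risk factors.
* HbA1c enters NORRISK 1 only through the multiplier cut-off; diabetes
  status and HbA1c are drawn as separate margins and are uncorrelated
  by default, so the diabetic tail of the HbA1c distribution is
  thinner than in real data.
* Eligibility is a binary decision; treatment sequencing (lifestyle
  first, drug thresholds, follow-up intervals) is out of scope.
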