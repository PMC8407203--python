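"""Regime comparison: stratified eligibility tables, percentage-point
deltas, Venn overlap partitions, cohort characteristics and the paired /
between-sex significance tests.

Reported percentages are rounded half-up to one decimal, matching how
such tables are conventionally printed; internal arithmetic is
unrounded, and deltas are returned on both scales.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    CohortError,
    MAN,
    REGIME_2009,
    REGIME_2017,
    REPORTING,
    RiskProfile,
    SEXES,
    WOMAN,
    assign_age_group,
    cohort_to_frame,
)
from .engines import (
    ModelCoefficients,
    NORRISK1,
    NORRISK2,
    default_coefficients,
    norrisk1_score,
    norrisk2_score,
)
from .rules import (
    EligibilityResult,
    ThresholdPolicy,
    classify_eligibility,
    default_policy,
)

_MODEL_FOR_REGIME = {REGIME_2009: NORRISK1, REGIME_2017: NORRISK2}

OVERALL = "all"


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal, as printed tables
    do (Python's round() is banker's rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Cohort classification
# ---------------------------------------------------------------------------

def classify_cohort(
    cohort: Sequence[RiskProfile],
    regime: str,
    policy: Optional[ThresholdPolicy] = None,
    coeffs: Optional[ModelCoefficients] = None,
    include_additional_factors: bool = True,
) -> list[EligibilityResult]:
    """Score and rule-check every profile under one regime, in order."""
    policy = policy if policy is not None else default_policy(regime)
    if policy.regime != regime:
        raise CohortError(
            f"policy regime {policy.regime!r} does not match {regime!r}")
    model = _MODEL_FOR_REGIME[regime]
    coeffs = coeffs if coeffs is not None else default_coefficients(model)
    results = []
    for profile in cohort:
        try:
            if model == NORRISK1:
                score = norrisk1_score(profile, coeffs,
                                       include_additional_factors)
            else:
                score = norrisk2_score(profile, coeffs)
            results.append(classify_eligibility(profile, score, policy))
        except Exception as exc:
            raise type(exc)(f"record {profile.id!r}: {exc}") from exc
    return results


# ---------------------------------------------------------------------------
# Eligibility tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellStats:
    """One table cell: per-row counts and reported percents.

    Counts may be absent when a cell was constructed from printed
    percentages only (then unrounded percents are unavailable too).
    """

    denominator: Optional[int]
    counts: Mapping[str, Optional[int]]
    percents: Mapping[str, float]
    unrounded: Mapping[str, Optional[float]]

    @classmethod
    def from_counts(cls, denominator: int,
                    counts: Mapping[str, int]) -> "CellStats":
        unrounded = {row: (100.0 * n / denominator if denominator else 0.0)
                     for row, n in counts.items()}
        percents = {row: round_half_up(v) for row, v in unrounded.items()}
        return cls(denominator=denominator, counts=dict(counts),
                   percents=percents, unrounded=unrounded)

    @classmethod
    def from_printed(cls, percents: Mapping[str, float],
                     counts: Optional[Mapping[str, Optional[int]]] = None,
                     denominator: Optional[int] = None) -> "CellStats":
        counts = dict(counts or {row: None for row in percents})
        unrounded = {
            row: (100.0 * counts[row] / denominator
                  if denominator and counts.get(row) is not None else None)
            for row in percents}
        return cls(denominator=denominator, counts=counts,
                   percents=dict(percents), unrounded=unrounded)


CellKey = tuple[str, str]  # (group: "all"/"woman"/"man", band: "all"/"40-49"/..)


@dataclass(frozen=True)
class CohortTable:
    """Stratified eligibility report for one regime.

    Rows: ``score_high``, one row per single-factor criterion counting
    individuals NOT score-high whose criterion triggered (rows are not
    mutually exclusive), and ``total_eligible`` counting the union once.
    Cells: overall, per sex, and per sex x reporting age band.
    """

    regime: str
    row_order: tuple[str, ...]
    cells: Mapping[CellKey, CellStats]

    def cell(self, group: str = OVERALL, band: str = OVERALL) -> CellStats:
        return self.cells[(group, band)]

    def percent(self, row: str, group: str = OVERALL,
                band: str = OVERALL) -> float:
        return self.cells[(group, band)].percents[row]

    def count(self, row: str, group: str = OVERALL,
              band: str = OVERALL) -> Optional[int]:
        return self.cells[(group, band)].counts.get(row)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (group, band), cell in self.cells.items():
            for row in self.row_order:
                if row not in cell.percents:
                    continue
                records.append({
                    "regime": self.regime, "group": group, "band": band,
                    "row": row, "n": cell.counts.get(row),
                    "percent": cell.percents[row],
                    "denominator": cell.denominator,
                })
        return pd.DataFrame.from_records(records)


def _cell_keys_for(profile: RiskProfile) -> list[CellKey]:
    band = assign_age_group(profile.age, REPORTING).label
    return [(OVERALL, OVERALL), (profile.sex, OVERALL), (profile.sex, band)]


def build_eligibility_table(
    cohort: Sequence[RiskProfile],
    regime: str,
    policy: Optional[ThresholdPolicy] = None,
    coeffs: Optional[ModelCoefficients] = None,
    include_additional_factors: bool = True,
    results: Optional[Sequence[EligibilityResult]] = None,
) -> CohortTable:
    """Tabulate score-high, per-criterion (among not score-high) and
    total-eligible proportions, overall and by sex x age band."""
    if not cohort:
        raise CohortError("cohort must be non-empty")
    policy = policy if policy is not None else default_policy(regime)
    if results is None:
        results = classify_cohort(cohort, regime, policy, coeffs,
                                  include_additional_factors)
    criterion_ids = [c.id for c in policy.criteria]
    row_order = ("score_high", *criterion_ids, "total_eligible")
    groups: dict[CellKey, dict[str, int]] = {}
    denominators: dict[CellKey, int] = {}
    for profile, res in zip(cohort, results):
        for key in _cell_keys_for(profile):
            counts = groups.setdefault(
                key, {row: 0 for row in row_order})
            denominators[key] = denominators.get(key, 0) + 1
            if res.score_high:
                counts["score_high"] += 1
            else:
                for cid in res.triggered_criteria:
                    counts[cid] += 1
            if res.eligible:
                counts["total_eligible"] += 1
    cells = {key: CellStats.from_counts(denominators[key], counts)
             for key, counts in groups.items()}
    return CohortTable(regime=regime, row_order=row_order, cells=cells)


@dataclass(frozen=True)
class DeltaResult:
    """B minus A for one cell/row, in percentage points, computed on the
    reported (1-decimal) percents and, when counts are available, on the
    unrounded proportions."""

    cell: CellKey
    row: str
    delta_reported: float
    delta_unrounded: Optional[float]


def percentage_point_delta(
    table_a: CohortTable,
    table_b: CohortTable,
    group: str = OVERALL,
    band: str = OVERALL,
    row: str = "total_eligible",
) -> DeltaResult:
    key = (group, band)
    if key not in table_a.cells or key not in table_b.cells:
        raise CohortError(f"cell {key} missing from one of the tables")
    a, b = table_a.cells[key], table_b.cells[key]
    if (a.denominator is not None and b.denominator is not None
            and a.denominator != b.denominator):
        raise CohortError(
            f"cell {key}: denominators differ ({a.denominator} vs "
            f"{b.denominator}); tables are not paired")
    delta_reported = round_half_up(b.percents[row] - a.percents[row])
    ua, ub = a.unrounded.get(row), b.unrounded.get(row)
    delta_unrounded = (ub - ua) if (ua is not None and ub is not None) else None
    return DeltaResult(cell=key, row=row, delta_reported=delta_reported,
                       delta_unrounded=delta_unrounded)


def scaled_impact(delta_pp: float, population_n: int) -> int:
    """Additional eligible individuals implied by a percentage-point
    delta in a population of the given size."""
    if population_n <= 0 or delta_pp < 0:
        raise CohortError("inputs must be positive")
    return int(round_half_up(population_n * delta_pp / 100.0, 0))


# ---------------------------------------------------------------------------
# Venn partition and paired test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VennPartition:
    """Two-classifier overlap partition; percentages of the full sample."""

    n_total: int
    only_a: int
    only_b: int
    both: int
    neither: int
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if self.only_a + self.only_b + self.both + self.neither != self.n_total:
            raise CohortError("Venn regions must sum to n_total")
        if min(self.only_a, self.only_b, self.both, self.neither) < 0:
            raise CohortError("Venn regions must be non-negative")

    def percents(self) -> dict[str, float]:
        if self.n_total == 0:
            return {k: 0.0 for k in ("only_a", "only_b", "both", "neither")}
        return {k: round_half_up(100.0 * getattr(self, k) / self.n_total)
                for k in ("only_a", "only_b", "both", "neither")}


def venn_partition(
    eligible_a: Sequence[bool],
    eligible_b: Sequence[bool],
    label_a: str = "A",
    label_b: str = "B",
) -> VennPartition:
    a = np.asarray(eligible_a, dtype=bool)
    b = np.asarray(eligible_b, dtype=bool)
    if a.shape != b.shape:
        raise CohortError("eligibility vectors must have equal length")
    return VennPartition(
        n_total=int(a.size),
        only_a=int(np.sum(a & ~b)),
        only_b=int(np.sum(~a & b)),
        both=int(np.sum(a & b)),
        neither=int(np.sum(~a & ~b)),
        label_a=label_a,
        label_b=label_b,
    )


@dataclass(frozen=True)
class PairedTestResult:
    """McNemar test on the discordant pairs of two paired classifications."""

    b: int  # A-only discordant count
    c: int  # B-only discordant count
    statistic: float
    p_value: float
    method: str


def mcnemar_test(
    eligible_a: Sequence[bool],
    eligible_b: Sequence[bool],
    exact_threshold: int = 25,
) -> PairedTestResult:
    """McNemar chi-squared without continuity correction,
    (b - c)^2 / (b + c) on 1 df; exact two-sided binomial when
    b + c < ``exact_threshold``; statistic 0 and p 1 when b + c = 0."""
    a = np.asarray(eligible_a, dtype=bool)
    bb = np.asarray(eligible_b, dtype=bool)
    if a.shape != bb.shape:
        raise CohortError("paired vectors must have equal length")
    return mcnemar_from_counts(int(np.sum(a & ~bb)), int(np.sum(~a & bb)),
                               exact_threshold=exact_threshold)


def mcnemar_from_counts(b: int, c: int,
                        exact_threshold: int = 25) -> PairedTestResult:
    n = b + c
    if n == 0:
        return PairedTestResult(b, c, 0.0, 1.0,
                                "degenerate (no discordant pairs)")
    statistic = (b - c) ** 2 / n
    if n < exact_threshold:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        method = f"exact binomial (b + c = {n} < {exact_threshold})"
    else:
        p = float(stats.chi2.sf(statistic, df=1))
        method = "chi-squared, 1 df, no continuity correction"
    return PairedTestResult(b, c, statistic, p, method)


# ---------------------------------------------------------------------------
# Between-sex tests and characteristics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexDifferenceResult:
    field: str
    statistic: float
    df: float
    p_value: float
    method: str


def sex_difference_tests(
    cohort: Union[Sequence[RiskProfile], pd.DataFrame],
    field: str,
) -> SexDifferenceResult:
    """Welch two-sample t for continuous fields; Pearson chi-squared
    (no continuity correction) on the 2x2 table for boolean flags."""
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    values = {sex: df.loc[df["sex"] == sex, field].dropna() for sex in SEXES}
    for sex, series in values.items():
        if series.empty:
            raise CohortError(f"no {sex} records with {field!r} present")
    sample = df[field].dropna()
    if sample.map(lambda v: isinstance(v, (bool, np.bool_))).all():
        table = np.array([
            [int(values[s].sum()), int((~values[s].astype(bool)).sum())]
            for s in SEXES])
        res = stats.chi2_contingency(table, correction=False)
        return SexDifferenceResult(field, float(res.statistic), float(res.dof),
                                   float(res.pvalue),
                                   "Pearson chi-squared, no continuity correction")
    res = stats.ttest_ind(values[WOMAN].astype(float),
                          values[MAN].astype(float), equal_var=False)
    return SexDifferenceResult(field, float(res.statistic), float(res.df),
                               float(res.pvalue), "Welch two-sample t")


_SUMMARY_CONTINUOUS = ("age", "sbp", "dbp", "total_chol", "ldl_chol",
                       "hdl_chol", "hba1c")
_SUMMARY_FLAGS = ("smoking", "diabetes", "antihypertensive_use",
                  "lipid_lowering_use", "family_history_mi",
                  "family_history_chd")


def summarize_characteristics(
    cohort: Union[Sequence[RiskProfile], pd.DataFrame],
) -> pd.DataFrame:
    """Table-style characteristics: mean (sd) for continuous fields and
    % (n) for flags, by sex x reporting band and overall. Optional
    ``bmi``/``waist`` columns add weight-category and abdominal-obesity
    rows (abdominal obesity: waist >= 88 cm in women, >= 102 cm in men).
    """
    df = (cohort.copy() if isinstance(cohort, pd.DataFrame)
          else cohort_to_frame(cohort))
    df["band"] = [assign_age_group(a, REPORTING).label for a in df["age"]]
    records = []

    def one_group(sub: pd.DataFrame, group: str, band: str) -> None:
        for name in _SUMMARY_CONTINUOUS:
            series = sub[name].dropna().astype(float)
            if series.empty:
                continue
            records.append({
                "group": group, "band": band, "variable": name,
                "kind": "continuous", "mean": float(series.mean()),
                "sd": (float(series.std(ddof=1)) if len(series) > 1 else None),
                "n": int(len(series)),
            })
        for name in _SUMMARY_FLAGS:
            series = sub[name].dropna()
            if series.empty:
                continue
            count = int(series.astype(bool).sum())
            records.append({
                "group": group, "band": band, "variable": name,
                "kind": "flag", "count": count,
                "percent": round_half_up(100.0 * count / len(series)),
                "n": int(len(series)),
            })
        if "bmi" in sub.columns:
            bmi = sub["bmi"].dropna().astype(float)
            if not bmi.empty:
                cats = {"bmi_normal": (bmi < 25).sum(),
                        "bmi_overweight": ((bmi >= 25) & (bmi < 30)).sum(),
                        "bmi_obese": (bmi >= 30).sum()}
                for var, count in cats.items():
                    records.append({
                        "group": group, "band": band, "variable": var,
                        "kind": "flag", "count": int(count),
                        "percent": round_half_up(100.0 * count / len(bmi)),
                        "n": int(len(bmi)),
                    })
        if "waist" in sub.columns:
            waist = sub[["waist", "sex"]].dropna()
            if not waist.empty:
                cut = waist["sex"].map({WOMAN: 88.0, MAN: 102.0})
                count = int((waist["waist"].astype(float) >= cut).sum())
                records.append({
                    "group": group, "band": band,
                    "variable": "abdominal_obesity", "kind": "flag",
                    "count": count,
                    "percent": round_half_up(100.0 * count / len(waist)),
                    "n": int(len(waist)),
                })

    one_group(df, OVERALL, OVERALL)
    for sex in SEXES:
        sub = df[df["sex"] == sex]
        if sub.empty:
            continue
        one_group(sub, sex, OVERALL)
        for band, band_df in sub.groupby("band"):
            one_group(band_df, sex, str(band))
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def venn_to_dict(partition: VennPartition) -> dict:
    return {
        "label_a": partition.label_a, "label_b": partition.label_b,
        "n_total": partition.n_total, "only_a": partition.only_a,
        "only_b": partition.only_b, "both": partition.both,
        "neither": partition.neither, "percents": partition.percents(),
    }


def render_venn(partition: VennPartition, path: str | Path) -> None:
    """Two-circle overlap figure with labelled region counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 4))
    sizes = {
        "a": partition.only_a + partition.both,
        "b": partition.only_b + partition.both,
    }
    scale = max(partition.n_total, 1)
    ra = 0.5 + 0.8 * (sizes["a"] / scale) ** 0.5
    rb = 0.5 + 0.8 * (sizes["b"] / scale) ** 0.5
    ax.add_patch(Circle((-0.6, 0), ra, alpha=0.4, color="tab:red"))
    ax.add_patch(Circle((0.6, 0), rb, alpha=0.4, color="tab:green"))
    ax.text(-1.1, 0, f"{partition.label_a}\n{partition.only_a}",
            ha="center", va="center")
    ax.text(1.1, 0, f"{partition.label_b}\n{partition.only_b}",
            ha="center", va="center")
    ax.text(0, 0, f"both\n{partition.both}", ha="center", va="center")
    ax.text(0, -1.9, f"neither: {partition.neither} of {partition.n_total}",
            ha="center")
    ax.set_xlim(-2.4, 2.4)
    ax.set_ylim(-2.2, 2.0)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
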