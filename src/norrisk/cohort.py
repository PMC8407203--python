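"""Participant data model, preprocessing and the study exclusion flow.

One row per participant: demographics, blood pressure, lipids, HbA1c,
smoking/diabetes status, family history and medication use — the inputs
required by the NORRISK 1 and NORRISK 2 ten-year cardiovascular risk
scores and the 2009/2017 Norwegian primary-prevention guideline rules.

Missing values are explicit (``None`` in memory, empty field in CSV);
a zero is never used as a missing marker because 0 is an impossible but
valid-looking clinical value.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

WOMAN = "woman"
MAN = "man"
SEXES = (WOMAN, MAN)

REGIME_2009 = "regime2009"
REGIME_2017 = "regime2017"
REGIMES = (REGIME_2009, REGIME_2017)

#: Age-band schemes (inclusive integer-year bounds; "40-49" covers
#: 40 <= floor(age) <= 49).
REPORTING = "reporting"
NORRISK1_THRESHOLDS = "norrisk1_thresholds"
NORRISK2_THRESHOLDS = "norrisk2_thresholds"

AGE_BAND_SCHEMES: dict[str, tuple[tuple[int, int], ...]] = {
    REPORTING: ((40, 49), (50, 59), (60, 69)),
    NORRISK1_THRESHOLDS: ((40, 49), (50, 59), (60, 69)),
    NORRISK2_THRESHOLDS: ((45, 54), (55, 64), (65, 74)),
}

#: Default plausibility bounds used by :func:`validate_profile` and, by
#: default, as truncation bounds by the synthetic-cohort generator.
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (20.0, 110.0),
    "sbp": (60.0, 260.0),
    "dbp": (30.0, 160.0),
    "total_chol": (1.5, 16.0),
    "ldl_chol": (0.3, 12.0),
    "hdl_chol": (0.3, 5.0),
    "hba1c": (2.5, 20.0),
}

#: Tolerance for the lipid consistency check ldl + hdl <= total + tol.
LIPID_TOLERANCE = 0.3

#: Profile fields each regime needs for score computation and rule
#: evaluation (sex and age are always required).
REQUIRED_FIELDS: dict[str, tuple[str, ...]] = {
    REGIME_2009: (
        "age", "sex", "sbp", "dbp", "total_chol", "smoking",
        "hba1c", "family_history_chd",
    ),
    REGIME_2017: (
        "age", "sex", "sbp", "dbp", "total_chol", "ldl_chol", "hdl_chol",
        "smoking", "diabetes", "family_history_mi", "antihypertensive_use",
    ),
}

BOOLEAN_FIELDS = (
    "smoking", "diabetes", "family_history_chd", "family_history_mi",
    "antihypertensive_use", "lipid_lowering_use", "prior_mi", "prior_stroke",
)
CONTINUOUS_FIELDS = (
    "age", "sbp", "dbp", "total_chol", "ldl_chol", "hdl_chol", "hba1c",
)

CSV_COLUMNS = (
    "id", "sex", "age", "sbp", "dbp", "total_chol", "ldl_chol", "hdl_chol",
    "hba1c", "smoking", "diabetes", "family_history_chd", "family_history_mi",
    "antihypertensive_use", "lipid_lowering_use", "prior_mi", "prior_stroke",
)


class CohortError(ValueError):
    """Raised for unusable records or out-of-range inputs."""


@dataclass(frozen=True)
class RiskProfile:
    """One participant's risk-factor vector.

    Units: age in years, blood pressures in mm Hg, cholesterol fractions
    in mmol/L, HbA1c in percent. Booleans are current status; ``None``
    marks a missing value.
    """

    id: str
    sex: Optional[str] = None
    age: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    total_chol: Optional[float] = None
    ldl_chol: Optional[float] = None
    hdl_chol: Optional[float] = None
    hba1c: Optional[float] = None
    smoking: Optional[bool] = None
    diabetes: Optional[bool] = None
    family_history_chd: Optional[bool] = None
    family_history_mi: Optional[bool] = None
    antihypertensive_use: Optional[bool] = None
    lipid_lowering_use: Optional[bool] = None
    prior_mi: Optional[bool] = None
    prior_stroke: Optional[bool] = None


@dataclass(frozen=True)
class BPReadingSet:
    """Ordered seated blood-pressure readings, (systolic, diastolic) mm Hg."""

    readings: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.readings:
            raise CohortError("BPReadingSet requires at least one reading")
        for sbp, dbp in self.readings:
            if not sbp > dbp:
                raise CohortError(
                    f"systolic must exceed diastolic, got ({sbp}, {dbp})"
                )


@dataclass(frozen=True)
class AnalysisBP:
    """Blood pressure used in analysis, flagged when derived from <3 readings."""

    sbp: float
    dbp: float
    degraded: bool = False


@dataclass(frozen=True)
class AgeBand:
    """Age band assignment; ``below_band`` marks ages mapped up into the
    lowest band of a scheme that starts above them."""

    label: str
    lo: int
    hi: int
    below_band: bool = False


@dataclass(frozen=True)
class ExclusionReport:
    """Stage tallies of the cohort exclusion flow."""

    n_input: int
    n_age_excluded: int
    n_prior_cvd_excluded: int
    n_invalid_excluded: int
    n_retained: int

    def __post_init__(self) -> None:
        counts = (self.n_input, self.n_age_excluded, self.n_prior_cvd_excluded,
                  self.n_invalid_excluded, self.n_retained)
        if any(c < 0 for c in counts):
            raise CohortError("exclusion counts must be non-negative")
        expected = (self.n_input - self.n_age_excluded
                    - self.n_prior_cvd_excluded - self.n_invalid_excluded)
        if self.n_retained != expected:
            raise CohortError(
                f"exclusion report does not reconcile: retained "
                f"{self.n_retained} != {expected}"
            )


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    message: str


def derive_analysis_bp(readings: BPReadingSet) -> AnalysisBP:
    """Collapse a reading set to the analysis blood pressure.

    With three readings the analysis value is the arithmetic mean of the
    final two, discarding the first (white-coat) reading. With two
    readings the mean of both is used and with a single reading that
    reading itself; both fallbacks are flagged ``degraded``.
    """
    r = readings.readings
    if len(r) >= 3:
        use, degraded = r[-2:], len(r) > 3
    elif len(r) == 2:
        use, degraded = r, True
    else:
        use, degraded = r, True
    sbp = sum(x[0] for x in use) / len(use)
    dbp = sum(x[1] for x in use) / len(use)
    return AnalysisBP(sbp=sbp, dbp=dbp, degraded=degraded)


def assign_age_group(age: float, scheme: str) -> AgeBand:
    """Map an age to its band under the given scheme.

    Bands are closed on integer years: "40-49" contains every age with
    40 <= floor(age) <= 49. Under ``norrisk2_thresholds`` ages 40-44 are
    mapped to the lowest band (45-54) with ``below_band=True`` since the
    score is applied from age 40 while its thresholds start at 45. Ages
    outside all bands raise :class:`CohortError` rather than clamping.
    """
    if scheme not in AGE_BAND_SCHEMES:
        raise CohortError(f"unknown age-band scheme {scheme!r}")
    bands = AGE_BAND_SCHEMES[scheme]
    year = math.floor(age)
    for lo, hi in bands:
        if lo <= year <= hi:
            return AgeBand(label=f"{lo}-{hi}", lo=lo, hi=hi)
    if scheme == NORRISK2_THRESHOLDS and 40 <= year < bands[0][0]:
        lo, hi = bands[0]
        return AgeBand(label=f"{lo}-{hi}", lo=lo, hi=hi, below_band=True)
    raise CohortError(
        f"age {age} outside the bands covered by scheme {scheme!r}"
    )


def validate_profile(
    profile: RiskProfile,
    regime: str,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
) -> list[ValidationIssue]:
    """Check presence and plausibility of the fields a regime needs.

    Returns an empty list iff the profile can be scored and rule-checked
    under the regime. Issues are data, not exceptions.
    """
    if regime not in REQUIRED_FIELDS:
        raise CohortError(f"unknown regime {regime!r}")
    bounds = {**PLAUSIBILITY_BOUNDS, **(bounds or {})}
    issues: list[ValidationIssue] = []
    for name in REQUIRED_FIELDS[regime]:
        value = getattr(profile, name)
        if value is None:
            issues.append(ValidationIssue(name, "missing"))
            continue
        if name == "sex":
            if value not in SEXES:
                issues.append(ValidationIssue(name, f"invalid sex {value!r}"))
            continue
        if name in bounds:
            lo, hi = bounds[name]
            if not (lo <= value <= hi):
                issues.append(ValidationIssue(
                    name, f"value {value} outside plausible range [{lo}, {hi}]"
                ))
    if profile.sbp is not None and profile.dbp is not None:
        if not profile.sbp > profile.dbp:
            issues.append(ValidationIssue(
                "sbp", f"systolic {profile.sbp} not above diastolic {profile.dbp}"
            ))
    if (profile.ldl_chol is not None and profile.hdl_chol is not None
            and profile.total_chol is not None):
        # 1e-9 guard so boundary sums are not rejected on float noise
        if (profile.ldl_chol + profile.hdl_chol
                > profile.total_chol + LIPID_TOLERANCE + 1e-9):
            issues.append(ValidationIssue(
                "ldl_chol",
                "ldl + hdl exceeds total cholesterol by more than "
                f"{LIPID_TOLERANCE} mmol/L",
            ))
    return issues


def apply_exclusions(
    cohort: Sequence[RiskProfile],
    max_age: float = 70.0,
) -> tuple[list[RiskProfile], ExclusionReport]:
    """Apply the study exclusion flow and tally each stage.

    Stages, in fixed order so tallies are well defined: (1) age >=
    ``max_age``; (2) prior myocardial infarction or stroke; (3) records
    failing :func:`validate_profile` for either regime's score
    computation. A record is counted only at the first stage it fails.
    """
    retained: list[RiskProfile] = []
    n_age = n_cvd = n_invalid = 0
    for p in cohort:
        if p.age is not None and p.age >= max_age:
            n_age += 1
            continue
        if bool(p.prior_mi) or bool(p.prior_stroke):
            n_cvd += 1
            continue
        if validate_profile(p, REGIME_2009) or validate_profile(p, REGIME_2017):
            n_invalid += 1
            continue
        retained.append(p)
    report = ExclusionReport(
        n_input=len(cohort),
        n_age_excluded=n_age,
        n_prior_cvd_excluded=n_cvd,
        n_invalid_excluded=n_invalid,
        n_retained=len(retained),
    )
    return retained, report


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

def _parse_float(text: str) -> Optional[float]:
    return float(text) if text != "" else None


def _parse_bool(text: str) -> Optional[bool]:
    if text == "":
        return None
    if text in ("0", "1"):
        return text == "1"
    raise CohortError(f"boolean fields must be '0'/'1' or empty, got {text!r}")


def _parse_sex(text: str) -> Optional[str]:
    if text == "":
        return None
    mapping = {"F": WOMAN, "M": MAN}
    if text not in mapping:
        raise CohortError(f"sex must be 'F' or 'M', got {text!r}")
    return mapping[text]


def profile_from_row(row: dict[str, str]) -> RiskProfile:
    """Build a profile from one CSV row (flat or triple-reading schema).

    The triple-reading variant carries ``sbp1..sbp3``/``dbp1..dbp3``
    instead of ``sbp``/``dbp``; present reading pairs are collapsed via
    :func:`derive_analysis_bp`.
    """
    kwargs: dict = {"id": row.get("id", "")}
    if "sbp1" in row and "sbp" not in row:
        pairs = []
        for i in (1, 2, 3):
            s, d = row.get(f"sbp{i}", ""), row.get(f"dbp{i}", "")
            if s != "" and d != "":
                pairs.append((float(s), float(d)))
        if pairs:
            bp = derive_analysis_bp(BPReadingSet(tuple(pairs)))
            kwargs["sbp"], kwargs["dbp"] = bp.sbp, bp.dbp
    else:
        kwargs["sbp"] = _parse_float(row.get("sbp", ""))
        kwargs["dbp"] = _parse_float(row.get("dbp", ""))
    kwargs["sex"] = _parse_sex(row.get("sex", ""))
    for name in ("age", "total_chol", "ldl_chol", "hdl_chol", "hba1c"):
        kwargs[name] = _parse_float(row.get(name, ""))
    for name in BOOLEAN_FIELDS:
        kwargs[name] = _parse_bool(row.get(name, ""))
    return RiskProfile(**kwargs)


def read_cohort_csv(path: str | Path) -> list[RiskProfile]:
    """Read a cohort CSV (flat or triple-reading schema) into profiles."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [profile_from_row({k: (v or "") for k, v in row.items()})
                for row in reader]


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_cohort_csv(cohort: Iterable[RiskProfile], path: str | Path) -> None:
    """Write profiles in the flat cohort CSV schema (F/M, 0/1, empty=missing)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for p in cohort:
            row = []
            for col in CSV_COLUMNS:
                value = getattr(p, col)
                if col == "sex" and value is not None:
                    value = {WOMAN: "F", MAN: "M"}[value]
                row.append(_format_value(value))
            writer.writerow(row)


def cohort_to_frame(cohort: Sequence[RiskProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame (one row each, columns = profile fields)."""
    records = [{f.name: getattr(p, f.name) for f in fields(RiskProfile)}
               for p in cohort]
    return pd.DataFrame.from_records(records, columns=[
        f.name for f in fields(RiskProfile)])
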