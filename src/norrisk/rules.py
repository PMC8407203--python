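"""2009 and 2017 guideline eligibility rules.

A regime combines an age-banded risk-score threshold scheme with
single-risk-factor criteria that confer eligibility regardless of the
score:

* 2009 (with NORRISK 1, bands 40-49/50-59/60-69, thresholds 1/5/10 %):
  total cholesterol >= 8 mmol/L, systolic BP >= 160 mm Hg or diastolic
  BP >= 100 mm Hg.
* 2017 (with NORRISK 2, bands 45-54/55-64/65-74): total cholesterol
  >= 7 mmol/L and LDL cholesterol >= 5 mmol/L (neither applies to women
  aged 50 or over), systolic BP >= 160 mm Hg, diastolic BP >= 100 mm Hg,
  and for people with diabetes LDL >= 2.5 mmol/L or blood pressure
  >= 140/90 mm Hg.

The sensitivity "international" hypertension mode replaces the plain BP
cut-offs 160/100 with 140/90 mm Hg. All comparisons are closed (>=).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .cohort import (
    CohortError,
    NORRISK1_THRESHOLDS,
    NORRISK2_THRESHOLDS,
    REGIME_2009,
    REGIME_2017,
    RiskProfile,
    WOMAN,
    assign_age_group,
)
from .engines import NORRISK1, NORRISK2, RiskResult

STANDARD = "standard"
INTERNATIONAL = "international"

_SCHEME_FOR_MODEL = {NORRISK1: NORRISK1_THRESHOLDS, NORRISK2: NORRISK2_THRESHOLDS}
_MODEL_FOR_REGIME = {REGIME_2009: NORRISK1, REGIME_2017: NORRISK2}

_CRITERION_KEYS = {"id", "field", "cutoff", "sbp_cutoff", "dbp_cutoff",
                   "requires_diabetes", "exempt_women_from_age",
                   "international_cutoff"}
_POLICY_KEYS = {"regime", "score_model", "hypertension_mode",
                "score_thresholds", "medium_thresholds", "criteria"}


class RuleError(ValueError):
    """Raised for malformed policies or unevaluable criteria."""


@dataclass(frozen=True)
class SingleFactorCriterion:
    """One guideline rule: a closed comparison on a profile field, or a
    combined blood-pressure rule (systolic OR diastolic at/above its
    cut-off). ``exempt_women_from_age`` makes the rule inapplicable to
    women at or above that age; ``requires_diabetes`` restricts it to
    people with diabetes; ``international_cutoff`` replaces the cut-off
    under the international hypertension definition."""

    id: str
    field: Optional[str] = None
    cutoff: Optional[float] = None
    sbp_cutoff: Optional[float] = None
    dbp_cutoff: Optional[float] = None
    requires_diabetes: bool = False
    exempt_women_from_age: Optional[float] = None
    international_cutoff: Optional[float] = None

    def applicable(self, sex: str, age: float) -> bool:
        """Total over every (sex, age): False only under the women's
        cholesterol exemption."""
        if (self.exempt_women_from_age is not None and sex == WOMAN
                and age >= self.exempt_women_from_age):
            return False
        return True


@dataclass(frozen=True)
class ThresholdPolicy:
    """A regime's score thresholds by age band plus its single-factor
    criteria, under one hypertension definition."""

    regime: str
    score_model: str
    score_thresholds: Mapping[str, float]
    criteria: tuple[SingleFactorCriterion, ...]
    hypertension_mode: str = STANDARD
    medium_thresholds: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.hypertension_mode not in (STANDARD, INTERNATIONAL):
            raise RuleError(
                f"unknown hypertension mode {self.hypertension_mode!r}")
        values = [self.score_thresholds[b]
                  for b in sorted(self.score_thresholds,
                                  key=lambda lbl: int(lbl.split("-")[0]))]
        if any(v <= 0 for v in values):
            raise RuleError("score thresholds must be strictly positive")
        if any(b > a for a, b in zip(values[1:], values[:-1])):
            raise RuleError("score thresholds must be non-decreasing with age")
        ids = [c.id for c in self.criteria]
        if len(ids) != len(set(ids)):
            raise RuleError("criterion ids must be unique")


@dataclass(frozen=True)
class EligibilityResult:
    """Per-participant decision under one regime.

    ``eligible`` = high score OR any triggered single-factor criterion;
    ``eligible_by_single_factor_only`` = not score-high but at least one
    criterion triggered. ``score_class`` is low/high for NORRISK 1 and
    low/medium/high for NORRISK 2 (medium does not affect eligibility).
    """

    regime: str
    score_percent: float
    score_class: str
    score_high: bool
    triggered_criteria: frozenset[str]
    eligible: bool
    eligible_by_single_factor_only: bool
    age_band: str
    below_band: bool = False


def _effective_cutoff(criterion: SingleFactorCriterion, mode: str) -> float:
    if mode == INTERNATIONAL and criterion.international_cutoff is not None:
        return criterion.international_cutoff
    return criterion.cutoff


def _require(profile: RiskProfile, criterion_id: str, name: str):
    value = getattr(profile, name)
    if value is None:
        raise RuleError(
            f"criterion {criterion_id!r} needs field {name!r}, missing in "
            f"profile {profile.id!r}"
        )
    return value


def evaluate_criteria(
    profile: RiskProfile, policy: ThresholdPolicy
) -> frozenset[str]:
    """Ids of the single-factor criteria the profile triggers.

    Criteria are evaluated independently; a profile may trigger several.
    A criterion triggers iff its applicability predicate holds for
    (sex, age), its diabetes condition (if any) holds, and the field
    comparison holds.
    """
    if profile.sex is None or profile.age is None:
        raise RuleError(f"profile {profile.id!r} lacks sex or age")
    triggered = set()
    for criterion in policy.criteria:
        if not criterion.applicable(profile.sex, profile.age):
            continue
        if criterion.requires_diabetes:
            if _require(profile, criterion.id, "diabetes") is not True:
                continue
        if criterion.field is not None:
            value = _require(profile, criterion.id, criterion.field)
            if float(value) >= _effective_cutoff(criterion,
                                                 policy.hypertension_mode):
                triggered.add(criterion.id)
        else:
            sbp = _require(profile, criterion.id, "sbp")
            dbp = _require(profile, criterion.id, "dbp")
            if (float(sbp) >= criterion.sbp_cutoff
                    or float(dbp) >= criterion.dbp_cutoff):
                triggered.add(criterion.id)
    return frozenset(triggered)


def classify_eligibility(
    profile: RiskProfile, score: RiskResult, policy: ThresholdPolicy
) -> EligibilityResult:
    """Combine score threshold and single-factor criteria into the
    regime's eligibility decision."""
    expected_model = _MODEL_FOR_REGIME[policy.regime]
    if score.model_id != expected_model:
        raise RuleError(
            f"regime {policy.regime!r} requires a {expected_model} score, "
            f"got {score.model_id!r}"
        )
    band = assign_age_group(profile.age, _SCHEME_FOR_MODEL[policy.score_model])
    try:
        threshold = policy.score_thresholds[band.label]
    except KeyError as exc:
        raise RuleError(f"no score threshold for band {band.label!r}") from exc
    score_high = score.final_score >= threshold
    if policy.score_model == NORRISK2:
        medium_from = (policy.medium_thresholds or {}).get(band.label)
        if score_high:
            score_class = "high"
        elif medium_from is not None and score.final_score >= medium_from:
            score_class = "medium"
        else:
            score_class = "low"
    else:
        score_class = "high" if score_high else "low"
    triggered = evaluate_criteria(profile, policy)
    eligible = score_high or bool(triggered)
    return EligibilityResult(
        regime=policy.regime,
        score_percent=score.final_score,
        score_class=score_class,
        score_high=score_high,
        triggered_criteria=triggered,
        eligible=eligible,
        eligible_by_single_factor_only=(not score_high) and bool(triggered),
        age_band=band.label,
        below_band=band.below_band,
    )


# ---------------------------------------------------------------------------
# Policy files
# ---------------------------------------------------------------------------

_POLICY_FILES = {REGIME_2009: "policy_2009.yaml", REGIME_2017: "policy_2017.yaml"}


def policy_from_dict(raw: Mapping) -> ThresholdPolicy:
    unknown = set(raw) - _POLICY_KEYS
    if unknown:
        raise RuleError(f"unknown policy keys: {sorted(unknown)}")
    criteria = []
    for spec in raw.get("criteria") or []:
        unknown = set(spec) - _CRITERION_KEYS
        if unknown:
            raise RuleError(
                f"unknown keys in criterion {spec.get('id')!r}: {sorted(unknown)}")
        criteria.append(SingleFactorCriterion(
            id=spec["id"],
            field=spec.get("field"),
            cutoff=(float(spec["cutoff"]) if spec.get("cutoff") is not None
                    else None),
            sbp_cutoff=(float(spec["sbp_cutoff"])
                        if spec.get("sbp_cutoff") is not None else None),
            dbp_cutoff=(float(spec["dbp_cutoff"])
                        if spec.get("dbp_cutoff") is not None else None),
            requires_diabetes=bool(spec.get("requires_diabetes", False)),
            exempt_women_from_age=(
                float(spec["exempt_women_from_age"])
                if spec.get("exempt_women_from_age") is not None else None),
            international_cutoff=(
                float(spec["international_cutoff"])
                if spec.get("international_cutoff") is not None else None),
        ))
    return ThresholdPolicy(
        regime=raw["regime"],
        score_model=raw["score_model"],
        score_thresholds={str(k): float(v)
                          for k, v in raw["score_thresholds"].items()},
        criteria=tuple(criteria),
        hypertension_mode=raw.get("hypertension_mode", STANDARD),
        medium_thresholds=(
            {str(k): float(v) for k, v in raw["medium_thresholds"].items()}
            if raw.get("medium_thresholds") else None),
    )


def policy_to_dict(policy: ThresholdPolicy) -> dict:
    return {
        "regime": policy.regime,
        "score_model": policy.score_model,
        "hypertension_mode": policy.hypertension_mode,
        "score_thresholds": dict(policy.score_thresholds),
        "medium_thresholds": (dict(policy.medium_thresholds)
                              if policy.medium_thresholds else None),
        "criteria": [
            {k: v for k, v in {
                "id": c.id,
                "field": c.field,
                "cutoff": c.cutoff,
                "sbp_cutoff": c.sbp_cutoff,
                "dbp_cutoff": c.dbp_cutoff,
                "requires_diabetes": c.requires_diabetes,
                "exempt_women_from_age": c.exempt_women_from_age,
                "international_cutoff": c.international_cutoff,
            }.items() if v is not None and v is not False}
            for c in policy.criteria
        ],
    }


def dump_policy(policy: ThresholdPolicy) -> str:
    """Canonical text form; packaged files round-trip bit-exactly."""
    return yaml.safe_dump(policy_to_dict(policy), sort_keys=False,
                          default_flow_style=False)


def load_policy(path: str | Path) -> ThresholdPolicy:
    with open(path) as fh:
        return policy_from_dict(yaml.safe_load(fh))


def default_policy(regime: str, hypertension_mode: str = STANDARD) -> ThresholdPolicy:
    """The packaged policy for a regime, under the requested hypertension
    definition (international mode lowers the plain BP cut-offs to
    140/90 mm Hg; cholesterol and diabetes rules are unchanged)."""
    try:
        name = _POLICY_FILES[regime]
    except KeyError as exc:
        raise RuleError(f"unknown regime {regime!r}") from exc
    ref = resources.files("norrisk").joinpath("configs", name)
    with resources.as_file(ref) as path:
        policy = load_policy(path)
    if hypertension_mode != policy.hypertension_mode:
        policy = replace(policy, hypertension_mode=hypertension_mode)
    return policy
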