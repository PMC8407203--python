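"""NORRISK 1 and NORRISK 2 risk-score engines.

Both scores are Cox-family risk equations

    risk% = 100 * (1 - S0 ** exp(lp - lp_ref)),   lp = sum_j beta_j * t_j(x_j)

with per-sex coefficients ``beta``, predictor transforms ``t_j``, 10-year
baseline survival ``S0`` and centering constant ``lp_ref``, all held in
versioned configuration. NORRISK 1 predicts 10-year risk of fatal
cardiovascular disease (predictors: age, systolic BP, total cholesterol,
daily smoking) and may be recalculated with multiplicative additional
factors (elevated HbA1c, family history of premature CHD). NORRISK 2
predicts 10-year risk of fatal plus non-fatal myocardial infarction and
stroke (adding low HDL by sex-specific cut-off, family history of
premature MI, and current antihypertensive use).

The engine itself contains no clinical constants: every coefficient,
cut-off, baseline survival and multiplier comes from a
:class:`ModelCoefficients` config. The packaged default configs are
synthetic calibrations (see ``configs/*_synthetic.yaml``): their
functional form and predictor sets follow the published models, but the
numeric values are package-authored stand-ins, not the published
coefficients.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from .cohort import (
    NORRISK1_THRESHOLDS,
    NORRISK2_THRESHOLDS,
    RiskProfile,
    SEXES,
    assign_age_group,
)

NORRISK1 = "norrisk1"
NORRISK2 = "norrisk2"

#: Profile fields each model's linear predictor may reference.
MODEL_PREDICTOR_FIELDS: dict[str, tuple[str, ...]] = {
    NORRISK1: ("age", "sbp", "total_chol", "smoking"),
    NORRISK2: ("age", "sbp", "total_chol", "smoking", "hdl_chol",
               "family_history_mi", "antihypertensive_use"),
}

_THRESHOLD_SCHEME = {NORRISK1: NORRISK1_THRESHOLDS, NORRISK2: NORRISK2_THRESHOLDS}

_TRANSFORM_TYPES = ("linear", "indicator", "below")
_TRANSFORM_KEYS = {"field", "type", "center", "scale", "cutoff"}
_MULTIPLIER_KEYS = {"id", "field", "op", "value", "factor"}
_SEX_KEYS = {"coefficients", "transforms", "baseline_survival", "lp_ref"}
_TOP_KEYS = {"model_id", "version", "description", "sex", "multipliers"}


class ConfigError(ValueError):
    """Raised for malformed or incomplete model configuration."""


class ScoringError(ValueError):
    """Raised when a profile cannot be scored under a config."""


@dataclass(frozen=True)
class Transform:
    """Predictor transform: how a raw profile field enters the lp.

    ``linear``: (x - center) / scale; ``indicator``: bool -> 0/1;
    ``below``: 1 if x < cutoff else 0 (e.g. the sex-specific low-HDL
    indicator).
    """

    field: str
    type: str
    center: float = 0.0
    scale: float = 1.0
    cutoff: Optional[float] = None

    def apply(self, value) -> float:
        if self.type == "linear":
            return (float(value) - self.center) / self.scale
        if self.type == "indicator":
            return 1.0 if value else 0.0
        if self.type == "below":
            return 1.0 if float(value) < self.cutoff else 0.0
        raise ConfigError(f"unknown transform type {self.type!r}")


@dataclass(frozen=True)
class Multiplier:
    """Additional-factor recalculation: multiply the risk percentage by
    ``factor`` when the condition on one profile field holds."""

    id: str
    field: str
    op: str  # "ge" or "is_true"
    factor: float
    value: Optional[float] = None

    def applies(self, profile: RiskProfile) -> bool:
        x = getattr(profile, self.field)
        if x is None:
            raise ScoringError(
                f"multiplier {self.id!r} needs field {self.field!r}, missing"
            )
        if self.op == "ge":
            return float(x) >= self.value
        if self.op == "is_true":
            return bool(x)
        raise ConfigError(f"unknown multiplier op {self.op!r}")


@dataclass(frozen=True)
class SexParameters:
    coefficients: Mapping[str, float]
    transforms: Mapping[str, Transform]
    baseline_survival: Union[float, Mapping[str, float]]
    lp_ref: float = 0.0


@dataclass(frozen=True)
class ModelCoefficients:
    """Versioned coefficient table fully defining one risk engine."""

    model_id: str
    version: str
    sex_params: Mapping[str, SexParameters]
    multipliers: tuple[Multiplier, ...] = ()
    description: str = ""

    def baseline_survival_for(self, sex: str, age: float) -> float:
        s0 = self.sex_params[sex].baseline_survival
        if isinstance(s0, Mapping):
            band = assign_age_group(age, _THRESHOLD_SCHEME[self.model_id])
            try:
                s0 = s0[band.label]
            except KeyError as exc:
                raise ConfigError(
                    f"no baseline survival for band {band.label!r}"
                ) from exc
        s0 = float(s0)
        if not 0.0 < s0 < 1.0:
            raise ConfigError(f"baseline survival {s0} outside (0, 1)")
        return s0


@dataclass(frozen=True)
class RiskResult:
    """Outcome of one score evaluation, in percent (0-100)."""

    model_id: str
    raw_score: float
    final_score: float
    applied_multipliers: tuple[str, ...]
    inputs_hash: str


def _validate_config(cfg: ModelCoefficients) -> None:
    if cfg.model_id not in MODEL_PREDICTOR_FIELDS:
        raise ConfigError(f"unknown model_id {cfg.model_id!r}")
    if not cfg.version:
        raise ConfigError("config version string must be non-empty")
    allowed = set(MODEL_PREDICTOR_FIELDS[cfg.model_id])
    for sex in SEXES:
        if sex not in cfg.sex_params:
            raise ConfigError(f"config lacks parameters for sex {sex!r}")
        params = cfg.sex_params[sex]
        for name in params.coefficients:
            if name not in params.transforms:
                raise ConfigError(
                    f"predictor {name!r} has a coefficient but no transform"
                )
        for name, tr in params.transforms.items():
            if name not in params.coefficients:
                raise ConfigError(
                    f"transform {name!r} has no matching coefficient"
                )
            if tr.field not in allowed:
                raise ConfigError(
                    f"transform {name!r} references field {tr.field!r} not "
                    f"declared for model {cfg.model_id!r}"
                )
            if tr.type not in _TRANSFORM_TYPES:
                raise ConfigError(f"unknown transform type {tr.type!r}")
            if tr.type == "below" and tr.cutoff is None:
                raise ConfigError(f"transform {name!r} of type 'below' needs a cutoff")
        s0 = params.baseline_survival
        values = s0.values() if isinstance(s0, Mapping) else [s0]
        for v in values:
            if not 0.0 < float(v) < 1.0:
                raise ConfigError(f"baseline survival {v} outside (0, 1)")
    for m in cfg.multipliers:
        if m.factor <= 0:
            raise ConfigError(f"multiplier {m.id!r} factor must be positive")
        if m.op == "ge" and m.value is None:
            raise ConfigError(f"multiplier {m.id!r} op 'ge' needs a value")


def load_coefficients(path: str | Path) -> ModelCoefficients:
    """Load and validate a coefficient config file; unknown keys refuse."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return coefficients_from_dict(raw)


def coefficients_from_dict(raw: Mapping) -> ModelCoefficients:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sex_params = {}
    for sex, block in (raw.get("sex") or {}).items():
        unknown = set(block) - _SEX_KEYS
        if unknown:
            raise ConfigError(f"unknown keys in sex block {sex!r}: {sorted(unknown)}")
        transforms = {}
        for name, spec in (block.get("transforms") or {}).items():
            unknown = set(spec) - _TRANSFORM_KEYS
            if unknown:
                raise ConfigError(
                    f"unknown keys in transform {name!r}: {sorted(unknown)}")
            transforms[name] = Transform(
                field=spec.get("field", name),
                type=spec["type"],
                center=float(spec.get("center", 0.0)),
                scale=float(spec.get("scale", 1.0)),
                cutoff=(float(spec["cutoff"]) if "cutoff" in spec
                        and spec["cutoff"] is not None else None),
            )
        sex_params[sex] = SexParameters(
            coefficients={k: float(v) for k, v in
                          (block.get("coefficients") or {}).items()},
            transforms=transforms,
            baseline_survival=block["baseline_survival"],
            lp_ref=float(block.get("lp_ref", 0.0)),
        )
    multipliers = []
    for spec in raw.get("multipliers") or []:
        unknown = set(spec) - _MULTIPLIER_KEYS
        if unknown:
            raise ConfigError(
                f"unknown keys in multiplier {spec.get('id')!r}: {sorted(unknown)}")
        multipliers.append(Multiplier(
            id=spec["id"], field=spec["field"], op=spec["op"],
            factor=float(spec["factor"]),
            value=(float(spec["value"]) if spec.get("value") is not None else None),
        ))
    cfg = ModelCoefficients(
        model_id=raw.get("model_id", ""),
        version=str(raw.get("version", "")),
        sex_params=sex_params,
        multipliers=tuple(multipliers),
        description=raw.get("description", ""),
    )
    _validate_config(cfg)
    return cfg


_DEFAULT_CONFIG_FILES = {
    NORRISK1: "norrisk1_synthetic.yaml",
    NORRISK2: "norrisk2_synthetic.yaml",
}


def default_coefficients(model_id: str) -> ModelCoefficients:
    """Packaged default (synthetic-calibration) config for a model."""
    try:
        name = _DEFAULT_CONFIG_FILES[model_id]
    except KeyError as exc:
        raise ConfigError(f"unknown model_id {model_id!r}") from exc
    ref = resources.files("norrisk").joinpath("configs", name)
    with resources.as_file(ref) as path:
        return load_coefficients(path)


def linear_predictor(profile: RiskProfile, coeffs: ModelCoefficients) -> float:
    """lp = sum of beta_j * transform_j(x_j) for the profile's sex."""
    if profile.sex not in coeffs.sex_params:
        raise ScoringError(f"no parameters for sex {profile.sex!r}")
    params = coeffs.sex_params[profile.sex]
    lp = 0.0
    for name, beta in params.coefficients.items():
        tr = params.transforms[name]
        value = getattr(profile, tr.field)
        if value is None:
            raise ScoringError(
                f"predictor {name!r} requires field {tr.field!r}, "
                f"missing in profile {profile.id!r}"
            )
        lp += beta * tr.apply(value)
    return lp


def cox_risk(lp: float, s0: float, lp_ref: float = 0.0) -> float:
    """10-year risk percentage 100 * (1 - S0 ** exp(lp - lp_ref))."""
    if not 0.0 < s0 < 1.0:
        raise ConfigError(f"baseline survival {s0} outside (0, 1)")
    return 100.0 * (1.0 - s0 ** math.exp(lp - lp_ref))


def _inputs_hash(profile: RiskProfile, coeffs: ModelCoefficients) -> str:
    payload = repr((coeffs.model_id, coeffs.version, profile))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _score(profile: RiskProfile, coeffs: ModelCoefficients,
           apply_multipliers: bool) -> RiskResult:
    lp = linear_predictor(profile, coeffs)
    params = coeffs.sex_params[profile.sex]
    s0 = coeffs.baseline_survival_for(profile.sex, profile.age)
    raw = cox_risk(lp, s0, params.lp_ref)
    applied: list[str] = []
    final = raw
    if apply_multipliers:
        for m in coeffs.multipliers:
            if m.applies(profile):
                final *= m.factor
                applied.append(m.id)
    final = min(final, 100.0)
    return RiskResult(
        model_id=coeffs.model_id,
        raw_score=raw,
        final_score=final,
        applied_multipliers=tuple(applied),
        inputs_hash=_inputs_hash(profile, coeffs),
    )


def norrisk1_score(
    profile: RiskProfile,
    coeffs: Optional[ModelCoefficients] = None,
    include_additional_factors: bool = True,
) -> RiskResult:
    """NORRISK 1: 10-year fatal CVD risk (%), ages 40-69.

    With ``include_additional_factors`` (the main-analysis mode) the raw
    score is multiplied by the configured factors whose conditions hold
    (elevated HbA1c, family history of premature CHD); without them (the
    sensitivity mode) the final score equals the raw score.
    """
    coeffs = coeffs if coeffs is not None else default_coefficients(NORRISK1)
    if coeffs.model_id != NORRISK1:
        raise ConfigError(f"expected a norrisk1 config, got {coeffs.model_id!r}")
    return _score(profile, coeffs, apply_multipliers=include_additional_factors)


def norrisk2_score(
    profile: RiskProfile,
    coeffs: Optional[ModelCoefficients] = None,
) -> RiskResult:
    """NORRISK 2: 10-year fatal + non-fatal MI/stroke risk (%), with the
    low-HDL indicator at sex-specific cut-offs and a score-increasing
    antihypertensive-use term. No ethnicity/rheumatoid multipliers are
    applied (the default config declares none)."""
    coeffs = coeffs if coeffs is not None else default_coefficients(NORRISK2)
    if coeffs.model_id != NORRISK2:
        raise ConfigError(f"expected a norrisk2 config, got {coeffs.model_id!r}")
    return _score(profile, coeffs, apply_multipliers=True)


def score_cohort(
    cohort: Sequence[RiskProfile],
    model_id: str,
    coeffs: Optional[ModelCoefficients] = None,
    include_additional_factors: bool = True,
) -> list[RiskResult]:
    """Score every profile with one model, preserving input order."""
    if model_id == NORRISK1:
        coeffs = coeffs if coeffs is not None else default_coefficients(NORRISK1)
        return [norrisk1_score(p, coeffs, include_additional_factors)
                for p in cohort]
    if model_id == NORRISK2:
        coeffs = coeffs if coeffs is not None else default_coefficients(NORRISK2)
        return [norrisk2_score(p, coeffs) for p in cohort]
    raise ConfigError(f"unknown model_id {model_id!r}")
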