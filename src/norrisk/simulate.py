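"""Seeded synthetic Tromso-like cohort generator.

The real survey data are third-party and unavailable, so downstream
stages are exercised on synthetic cohorts whose sex x age-band strata
reproduce published marginal risk-factor distributions: means/SDs for
total/LDL/HDL cholesterol, systolic/diastolic blood pressure and HbA1c,
and prevalences for smoking, diabetes and antihypertensive/
lipid-lowering drug use. Joints are imposed by a Gaussian copula: a
latent multivariate normal with a configurable per-stratum correlation
matrix; continuous margins are affine maps of the latent normals
(truncated to plausibility bounds by rejection), binary margins
dichotomize their latent at the quantile matching the target prevalence
(probit link), and ages are uniform within the band. Lipid consistency
(ldl + hdl <= total + 0.3 mmol/L) is enforced by resampling violators.

Default correlations (total-LDL 0.9, systolic-diastolic 0.7, total-HDL
0.1, age-systolic 0.25, others 0) and the family-history prevalences
are modelling choices, not published values; they are explicit in the
spec and swappable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.special import ndtr, ndtri

from .cohort import (
    CohortError,
    MAN,
    PLAUSIBILITY_BOUNDS,
    RiskProfile,
    WOMAN,
)

#: Latent variable order: continuous first, then binary latents.
CONTINUOUS_VARS = ("age", "sbp", "dbp", "total_chol", "ldl_chol",
                   "hdl_chol", "hba1c")
BINARY_VARS = ("smoking", "diabetes", "antihypertensive_use",
               "lipid_lowering_use", "family_history_mi",
               "family_history_chd")
VARS = CONTINUOUS_VARS + BINARY_VARS

DEFAULT_CORRELATIONS: dict[frozenset, float] = {
    frozenset(("total_chol", "ldl_chol")): 0.9,
    frozenset(("sbp", "dbp")): 0.7,
    frozenset(("total_chol", "hdl_chol")): 0.1,
    frozenset(("age", "sbp")): 0.25,
}

LIPID_TOLERANCE = 0.3

#: Decimal places used when rounding generated values.
_ROUNDING = {"age": 1, "sbp": 1, "dbp": 1, "total_chol": 2, "ldl_chol": 2,
             "hdl_chol": 2, "hba1c": 2}


class GenerationError(ValueError):
    """Raised for infeasible generator specifications."""


@dataclass(frozen=True)
class StratumSpec:
    """Targets for one sex x age-band stratum."""

    sex: str
    age_band: tuple[int, int]
    n: int
    continuous_targets: Mapping[str, tuple[float, float]]
    prevalence_targets: Mapping[str, float]
    correlations: Mapping[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    truncation_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PLAUSIBILITY_BOUNDS))

    def __post_init__(self) -> None:
        if self.n < 0:
            raise GenerationError("stratum n must be non-negative")
        for name, (mean, sd) in self.continuous_targets.items():
            if sd <= 0:
                raise GenerationError(f"{name} sd must be positive, got {sd}")
        for name, p in self.prevalence_targets.items():
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"{name} prevalence {p} outside [0, 1]")

    def correlation_matrix(self) -> np.ndarray:
        """Unit-diagonal correlation matrix over :data:`VARS`;
        positive-definiteness is checked via Cholesky."""
        k = len(VARS)
        r = np.eye(k)
        index = {v: i for i, v in enumerate(VARS)}
        for pair, rho in self.correlations.items():
            a, b = tuple(pair)
            i, j = index[a], index[b]
            r[i, j] = r[j, i] = rho
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError as exc:
            raise GenerationError("correlation matrix not positive definite") from exc
        return r


@dataclass(frozen=True)
class GeneratorSpec:
    strata: tuple[StratumSpec, ...]
    seed: int
    id_prefix: str = "SYN"
    enforce_lipid_consistency: bool = True

    def __post_init__(self) -> None:
        cells = [(s.sex, s.age_band) for s in self.strata]
        if len(cells) != len(set(cells)):
            raise GenerationError("strata must cover disjoint (sex, band) cells")


# ---------------------------------------------------------------------------
# Published-table calibration (marginal targets per sex x band stratum)
# ---------------------------------------------------------------------------

#: (sex, band, count, {field: (mean, sd)}, {field: prevalence}).
#: The family-history prevalences are package placeholders, not
#: published values; nothing downstream depends on them numerically.
_TROMSO_STRATA = (
    (WOMAN, (40, 49), 3286,
     {"sbp": (116.5, 14.6), "dbp": (71.2, 9.3), "total_chol": (5.1, 0.9),
      "ldl_chol": (3.2, 0.9), "hdl_chol": (1.6, 0.4), "hba1c": (5.4, 0.5)},
     {"smoking": 0.127, "diabetes": 0.020, "antihypertensive_use": 0.068,
      "lipid_lowering_use": 0.015}),
    (WOMAN, (50, 59), 3115,
     {"sbp": (123.0, 17.6), "dbp": (73.3, 9.7), "total_chol": (5.7, 1.0),
      "ldl_chol": (3.7, 0.9), "hdl_chol": (1.7, 0.5), "hba1c": (5.6, 0.6)},
     {"smoking": 0.180, "diabetes": 0.029, "antihypertensive_use": 0.145,
      "lipid_lowering_use": 0.069}),
    (WOMAN, (60, 69), 2495,
     {"sbp": (132.6, 20.5), "dbp": (73.7, 9.7), "total_chol": (5.9, 1.0),
      "ldl_chol": (3.8, 1.0), "hdl_chol": (1.8, 0.5), "hba1c": (5.7, 0.5)},
     {"smoking": 0.155, "diabetes": 0.049, "antihypertensive_use": 0.285,
      "lipid_lowering_use": 0.178}),
    (MAN, (40, 49), 2943,
     {"sbp": (126.8, 14.8), "dbp": (77.5, 9.4), "total_chol": (5.5, 1.0),
      "ldl_chol": (3.7, 0.9), "hdl_chol": (1.3, 0.4), "hba1c": (5.5, 0.6)},
     {"smoking": 0.127, "diabetes": 0.024, "antihypertensive_use": 0.073,
      "lipid_lowering_use": 0.036}),
    (MAN, (50, 59), 2579,
     {"sbp": (131.0, 17.1), "dbp": (79.9, 9.8), "total_chol": (5.6, 1.0),
      "ldl_chol": (3.9, 0.9), "hdl_chol": (1.4, 0.4), "hba1c": (5.7, 0.6)},
     {"smoking": 0.158, "diabetes": 0.042, "antihypertensive_use": 0.160,
      "lipid_lowering_use": 0.085}),
    (MAN, (60, 69), 2148,
     {"sbp": (136.5, 18.3), "dbp": (79.7, 9.5), "total_chol": (5.5, 1.0),
      "ldl_chol": (3.7, 0.9), "hdl_chol": (1.5, 0.4), "hba1c": (5.8, 0.7)},
     {"smoking": 0.135, "diabetes": 0.066, "antihypertensive_use": 0.349,
      "lipid_lowering_use": 0.176}),
)

#: Placeholder family-history prevalences (no published source).
_FAMILY_HISTORY_DEFAULTS = {"family_history_mi": 0.10,
                            "family_history_chd": 0.15}

_REFERENCE_TOTAL = sum(s[2] for s in _TROMSO_STRATA)


def default_tromso_spec(total_n: int, seed: int = 0,
                        id_prefix: str = "SYN") -> GeneratorSpec:
    """Generator spec calibrated to the published sex x age-band strata.

    Stratum sizes are apportioned proportionally to the published counts
    (largest-remainder rounding so they sum to ``total_n``).
    """
    if total_n <= 0:
        raise GenerationError("total_n must be positive")
    quotas = [total_n * c / _REFERENCE_TOTAL for _, _, c, _, _ in _TROMSO_STRATA]
    sizes = [math.floor(q) for q in quotas]
    remainders = sorted(range(len(quotas)),
                        key=lambda i: quotas[i] - sizes[i], reverse=True)
    for i in remainders[: total_n - sum(sizes)]:
        sizes[i] += 1
    strata = []
    for (sex, band, _, cont, prev), n in zip(_TROMSO_STRATA, sizes):
        strata.append(StratumSpec(
            sex=sex, age_band=band, n=n,
            continuous_targets=dict(cont),
            prevalence_targets={**prev, **_FAMILY_HISTORY_DEFAULTS},
        ))
    return GeneratorSpec(strata=tuple(strata), seed=seed, id_prefix=id_prefix)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _check_feasible(stratum: StratumSpec) -> None:
    for name, (mean, sd) in stratum.continuous_targets.items():
        if name not in stratum.truncation_bounds:
            continue
        lo, hi = stratum.truncation_bounds[name]
        if mean < lo - 6 * sd or mean > hi + 6 * sd:
            raise GenerationError(
                f"{name}: bounds [{lo}, {hi}] exclude mean {mean} by > 6 sd")


def _generate_stratum(stratum: StratumSpec, rng: np.random.Generator,
                      enforce_lipid: bool) -> dict[str, np.ndarray]:
    _check_feasible(stratum)
    if stratum.n == 0:
        return {v: np.empty(0) for v in VARS}
    index = {v: i for i, v in enumerate(VARS)}
    chol = np.linalg.cholesky(stratum.correlation_matrix())
    lo_age, hi_age = stratum.age_band
    out: dict[str, list[np.ndarray]] = {v: [] for v in VARS}
    needed = stratum.n
    for _round in range(200):
        if needed <= 0:
            break
        m = max(2 * needed + 16, 64)
        z = rng.standard_normal((m, len(VARS))) @ chol.T
        u = ndtr(z)
        values: dict[str, np.ndarray] = {}
        values["age"] = np.round(
            lo_age + u[:, index["age"]] * (hi_age + 1 - lo_age), _ROUNDING["age"])
        for name in CONTINUOUS_VARS:
            if name == "age":
                continue
            mean, sd = stratum.continuous_targets[name]
            values[name] = np.round(mean + sd * z[:, index[name]],
                                    _ROUNDING[name])
        for name in BINARY_VARS:
            p = stratum.prevalence_targets.get(name, 0.0)
            values[name] = u[:, index[name]] > 1.0 - p
        mask = (values["age"] >= lo_age) & (values["age"] < hi_age + 1)
        for name in CONTINUOUS_VARS:
            if name in stratum.truncation_bounds:
                b_lo, b_hi = stratum.truncation_bounds[name]
                mask &= (values[name] >= b_lo) & (values[name] <= b_hi)
        mask &= values["sbp"] > values["dbp"]
        if enforce_lipid:
            mask &= (values["ldl_chol"] + values["hdl_chol"]
                     <= values["total_chol"] + LIPID_TOLERANCE + 1e-9)
        take = min(int(mask.sum()), needed)
        if take:
            idx = np.flatnonzero(mask)[:take]
            for name in VARS:
                out[name].append(values[name][idx])
            needed -= take
    if needed > 0:
        raise GenerationError(
            f"stratum ({stratum.sex}, {stratum.age_band}) infeasible: "
            f"could not draw {stratum.n} admissible records")
    return {v: np.concatenate(out[v]) if out[v] else np.empty(0)
            for v in VARS}


def generate_cohort(spec: GeneratorSpec) -> list[RiskProfile]:
    """Draw a cohort; fully reproducible from ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.strata))
    profiles: list[RiskProfile] = []
    counter = 0
    for stratum, child in zip(spec.strata, children):
        rng = np.random.default_rng(child)
        cols = _generate_stratum(stratum, rng, spec.enforce_lipid_consistency)
        for i in range(len(cols["age"])):
            counter += 1
            profiles.append(RiskProfile(
                id=f"{spec.id_prefix}{counter:06d}",
                sex=stratum.sex,
                age=float(cols["age"][i]),
                sbp=float(cols["sbp"][i]),
                dbp=float(cols["dbp"][i]),
                total_chol=float(cols["total_chol"][i]),
                ldl_chol=float(cols["ldl_chol"][i]),
                hdl_chol=float(cols["hdl_chol"][i]),
                hba1c=float(cols["hba1c"][i]),
                smoking=bool(cols["smoking"][i]),
                diabetes=bool(cols["diabetes"][i]),
                antihypertensive_use=bool(cols["antihypertensive_use"][i]),
                lipid_lowering_use=bool(cols["lipid_lowering_use"][i]),
                family_history_mi=bool(cols["family_history_mi"][i]),
                family_history_chd=bool(cols["family_history_chd"][i]),
                prior_mi=False,
                prior_stroke=False,
            ))
    return profiles


def plant_exclusions(
    cohort: Sequence[RiskProfile],
    n_over_age: int,
    n_prior_cvd: int,
    n_invalid: int,
    seed: int = 0,
) -> list[RiskProfile]:
    """Append records engineered to fail each exclusion stage exactly as
    counted (over-age; prior MI/stroke at an includable age; missing a
    score predictor), deterministically shuffled."""
    if min(n_over_age, n_prior_cvd, n_invalid) < 0:
        raise GenerationError("planted counts must be non-negative")
    template = cohort[0] if cohort else RiskProfile(
        id="T", sex=MAN, age=55.0, sbp=130.0, dbp=80.0, total_chol=5.5,
        ldl_chol=3.5, hdl_chol=1.4, hba1c=5.5, smoking=False, diabetes=False,
        family_history_chd=False, family_history_mi=False,
        antihypertensive_use=False, lipid_lowering_use=False,
        prior_mi=False, prior_stroke=False)
    planted: list[RiskProfile] = []
    for i in range(n_over_age):
        planted.append(replace(template, id=f"XAGE{i:05d}", age=75.0,
                               prior_mi=False, prior_stroke=False))
    for i in range(n_prior_cvd):
        planted.append(replace(template, id=f"XCVD{i:05d}", age=55.0,
                               prior_mi=(i % 2 == 0),
                               prior_stroke=(i % 2 == 1)))
    for i in range(n_invalid):
        planted.append(replace(template, id=f"XINV{i:05d}", age=55.0,
                               prior_mi=False, prior_stroke=False,
                               total_chol=None))
    combined = list(cohort) + planted
    order = np.random.default_rng(seed).permutation(len(combined))
    return [combined[i] for i in order]


# ---------------------------------------------------------------------------
# Moment-recovery tolerances
# ---------------------------------------------------------------------------

def _lipid_bias_bound(stratum: StratumSpec, name: str) -> float:
    """Analytic bound on the mean shift the lipid-consistency resampling
    induces on one lipid field.

    The acceptance region is approximated as the Gaussian half-space
    D = ldl + hdl - total - tol <= 0; conditioning a jointly normal X on
    that half-space shifts its mean by corr(X, D) * sd_X * phi(z)/Phi(z)
    with z the standardized cut point. Doubled for the Gaussian-
    approximation slack.
    """
    if name not in ("total_chol", "ldl_chol", "hdl_chol"):
        return 0.0
    t = stratum.continuous_targets
    m_t, s_t = t["total_chol"]
    m_l, s_l = t["ldl_chol"]
    m_h, s_h = t["hdl_chol"]

    def rho(a: str, b: str) -> float:
        return stratum.correlations.get(frozenset((a, b)), 0.0)

    var_d = (s_l ** 2 + s_h ** 2 + s_t ** 2
             + 2 * rho("ldl_chol", "hdl_chol") * s_l * s_h
             - 2 * rho("total_chol", "ldl_chol") * s_t * s_l
             - 2 * rho("total_chol", "hdl_chol") * s_t * s_h)
    if var_d <= 0:
        return 0.0
    sd_d = math.sqrt(var_d)
    mean_d = m_l + m_h - m_t - LIPID_TOLERANCE
    cov = {
        "ldl_chol": (s_l ** 2 + rho("ldl_chol", "hdl_chol") * s_l * s_h
                     - rho("total_chol", "ldl_chol") * s_t * s_l),
        "hdl_chol": (s_h ** 2 + rho("ldl_chol", "hdl_chol") * s_l * s_h
                     - rho("total_chol", "hdl_chol") * s_t * s_h),
        "total_chol": (rho("total_chol", "ldl_chol") * s_t * s_l
                       + rho("total_chol", "hdl_chol") * s_t * s_h
                       - s_t ** 2),
    }[name]
    z = -mean_d / sd_d  # standardized upper cut of the kept region
    keep = float(ndtr(z))
    if keep <= 0.0:
        return 0.0
    lam = math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi) / keep
    return 2.0 * abs(cov / sd_d) * lam


def _bounds_bias_bound(stratum: StratumSpec, name: str) -> float:
    """Bound on the mean shift from truncating a field to its bounds:
    sd * phi(a)/Phi(a) per side at standardized distance a, doubled."""
    if name not in stratum.truncation_bounds:
        return 0.0
    mean, sd = stratum.continuous_targets[name]
    lo, hi = stratum.truncation_bounds[name]
    total = 0.0
    for a in ((mean - lo) / sd, (hi - mean) / sd):
        if a < 8.0:
            keep = float(ndtr(a))
            if keep > 0:
                total += sd * math.exp(-0.5 * a * a) / math.sqrt(2 * math.pi) / keep
    return 2.0 * total


def moment_tolerance(spec: GeneratorSpec, stratum: StratumSpec,
                     name: str) -> float:
    """Tolerance for |sample mean - target mean| in a recovery check:
    3 sd/sqrt(n) sampling noise plus the documented analytic bias bounds
    for bound truncation and (when enforced) lipid-consistency
    resampling."""
    mean, sd = stratum.continuous_targets[name]
    tol = 3.0 * sd / math.sqrt(max(stratum.n, 1))
    tol += _bounds_bias_bound(stratum, name)
    if spec.enforce_lipid_consistency:
        tol += _lipid_bias_bound(stratum, name)
    return tol


# ---------------------------------------------------------------------------
# Spec files
# ---------------------------------------------------------------------------

def spec_to_dict(spec: GeneratorSpec) -> dict:
    return {
        "seed": spec.seed,
        "id_prefix": spec.id_prefix,
        "enforce_lipid_consistency": spec.enforce_lipid_consistency,
        "strata": [
            {
                "sex": s.sex,
                "age_band": list(s.age_band),
                "n": s.n,
                "continuous_targets": {k: list(v)
                                       for k, v in s.continuous_targets.items()},
                "prevalence_targets": dict(s.prevalence_targets),
                "correlations": [{"pair": sorted(p), "rho": r}
                                 for p, r in s.correlations.items()],
                "truncation_bounds": {k: list(v)
                                      for k, v in s.truncation_bounds.items()},
            }
            for s in spec.strata
        ],
    }


def spec_from_dict(raw: Mapping) -> GeneratorSpec:
    strata = []
    for block in raw["strata"]:
        strata.append(StratumSpec(
            sex=block["sex"],
            age_band=tuple(block["age_band"]),
            n=int(block["n"]),
            continuous_targets={k: tuple(v) for k, v in
                                block["continuous_targets"].items()},
            prevalence_targets=dict(block["prevalence_targets"]),
            correlations={frozenset(c["pair"]): float(c["rho"])
                          for c in block.get("correlations", [])},
            truncation_bounds={k: tuple(v) for k, v in
                               block.get("truncation_bounds",
                                         PLAUSIBILITY_BOUNDS).items()},
        ))
    return GeneratorSpec(
        strata=tuple(strata),
        seed=int(raw["seed"]),
        id_prefix=raw.get("id_prefix", "SYN"),
        enforce_lipid_consistency=bool(
            raw.get("enforce_lipid_consistency", True)),
    )


def save_generator_spec(spec: GeneratorSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_generator_spec(path: str | Path) -> GeneratorSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
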