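"""Independent brute-force oracles for the guideline rule engines.

Each regime's criteria are re-expressed as one flat boolean expression,
written directly from the rule definitions and kept deliberately
separate from the package's policy/criterion machinery.
"""
from norrisk.cohort import RiskProfile, WOMAN

INTERNATIONAL = "international"


def oracle_2009_criteria(p: RiskProfile, mode: str) -> set[str]:
    sbp_cut, dbp_cut = (140.0, 90.0) if mode == INTERNATIONAL else (160.0, 100.0)
    triggered = set()
    if p.total_chol >= 8.0:
        triggered.add("total_chol_ge_8")
    if p.sbp >= sbp_cut:
        triggered.add("sbp_ge_160")
    if p.dbp >= dbp_cut:
        triggered.add("dbp_ge_100")
    return triggered


def oracle_2017_criteria(p: RiskProfile, mode: str) -> set[str]:
    sbp_cut, dbp_cut = (140.0, 90.0) if mode == INTERNATIONAL else (160.0, 100.0)
    woman_exempt = p.sex == WOMAN and p.age >= 50.0
    triggered = set()
    if not woman_exempt and p.total_chol >= 7.0:
        triggered.add("total_chol_ge_7")
    if not woman_exempt and p.ldl_chol >= 5.0:
        triggered.add("ldl_ge_5")
    if p.sbp >= sbp_cut:
        triggered.add("sbp_ge_160")
    if p.dbp >= dbp_cut:
        triggered.add("dbp_ge_100")
    if p.diabetes and p.ldl_chol >= 2.5:
        triggered.add("diabetes_ldl_ge_2_5")
    if p.diabetes and (p.sbp >= 140.0 or p.dbp >= 90.0):
        triggered.add("diabetes_bp_ge_140_90")
    return triggered


def oracle_score_threshold(regime: str, age: float) -> float:
    if regime == "regime2009":
        if age < 50:
            return 1.0
        if age < 60:
            return 5.0
        return 10.0
    if age < 55:  # ages 40-44 use the lowest (45-54) threshold
        return 5.0
    if age < 65:
        return 10.0
    return 15.0


def boundary_grid():
    """Profiles spanning every cut-off boundary for both regimes.

    Cross product of sex, ages straddling the age-dependent rules, and
    values just below / at / above every cholesterol and blood-pressure
    cut-off, with and without diabetes.
    """
    from conftest import make_profile

    ages = (40.0, 45.0, 49.9, 50.0, 55.0, 69.0)
    tchols = (6.9, 7.0, 7.1, 7.9, 8.0, 8.1)
    ldls = (2.4, 2.5, 2.6, 4.9, 5.0, 5.1)
    sbps = (130.0, 139.0, 140.0, 160.0, 161.0)
    dbps = (70.0, 89.0, 90.0, 100.0, 101.0)
    profiles = []
    for sex in ("woman", "man"):
        for age in ages:
            for tchol in tchols:
                for ldl in ldls:
                    for sbp in sbps:
                        for dbp in dbps:
                            for diabetes in (False, True):
                                profiles.append(make_profile(
                                    id=f"G{len(profiles)}", sex=sex, age=age,
                                    total_chol=tchol, ldl_chol=ldl,
                                    sbp=sbp, dbp=dbp, diabetes=diabetes))
    return profiles
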