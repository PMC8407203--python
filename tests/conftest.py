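from importlib import resources

import pytest
from hypothesis import HealthCheck, settings

from norrisk.cohort import MAN, RiskProfile, WOMAN, read_cohort_csv
from norrisk.engines import coefficients_from_dict

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def validation_cohort():
    """Frozen synthetic validation cohort shipped with the package."""
    ref = resources.files("norrisk").joinpath(
        "data", "validation_cohort_synthetic.csv")
    with resources.as_file(ref) as path:
        return read_cohort_csv(path)


def make_profile(**overrides) -> RiskProfile:
    """A complete, in-range reference profile for targeted edits."""
    base = dict(
        id="P1", sex=MAN, age=55.0, sbp=130.0, dbp=80.0, total_chol=5.5,
        ldl_chol=3.5, hdl_chol=1.4, hba1c=5.5, smoking=False, diabetes=False,
        family_history_chd=False, family_history_mi=False,
        antihypertensive_use=False, lipid_lowering_use=False,
        prior_mi=False, prior_stroke=False)
    base.update(overrides)
    return RiskProfile(**base)


@pytest.fixture
def profile():
    return make_profile()


#: Frozen engine config used wherever a test asserts an exact numeric
#: score, so assertions never depend on the packaged clinical defaults.
FROZEN_NORRISK1 = {
    "model_id": "norrisk1",
    "version": "test-frozen-1",
    "sex": {
        sex: {
            "coefficients": {"age": 0.1, "sbp": 0.2, "total_chol": 0.3,
                             "smoking": 0.5},
            "transforms": {
                "age": {"field": "age", "type": "linear", "center": 50.0},
                "sbp": {"field": "sbp", "type": "linear", "center": 120.0,
                        "scale": 10.0},
                "total_chol": {"field": "total_chol", "type": "linear",
                               "center": 5.0},
                "smoking": {"field": "smoking", "type": "indicator"},
            },
            "baseline_survival": 0.95,
            "lp_ref": 0.0,
        }
        for sex in (WOMAN, MAN)
    },
    "multipliers": [
        {"id": "hba1c_elevated", "field": "hba1c", "op": "ge",
         "value": 6.0, "factor": 1.5},
        {"id": "family_history_premature_chd", "field": "family_history_chd",
         "op": "is_true", "value": None, "factor": 2.0},
    ],
}

FROZEN_NORRISK2 = {
    "model_id": "norrisk2",
    "version": "test-frozen-2",
    "sex": {
        sex: {
            "coefficients": {"age": 0.08, "sbp": 0.15, "total_chol": 0.2,
                             "smoking": 0.4, "low_hdl": 0.3,
                             "family_history_mi": 0.35,
                             "antihypertensive_use": 0.25},
            "transforms": {
                "age": {"field": "age", "type": "linear", "center": 55.0},
                "sbp": {"field": "sbp", "type": "linear", "center": 130.0,
                        "scale": 10.0},
                "total_chol": {"field": "total_chol", "type": "linear",
                               "center": 6.0},
                "smoking": {"field": "smoking", "type": "indicator"},
                "low_hdl": {"field": "hdl_chol", "type": "below",
                            "cutoff": 1.3 if sex == WOMAN else 1.0},
                "family_history_mi": {"field": "family_history_mi",
                                      "type": "indicator"},
                "antihypertensive_use": {"field": "antihypertensive_use",
                                         "type": "indicator"},
            },
            "baseline_survival": 0.9,
            "lp_ref": 0.0,
        }
        for sex in (WOMAN, MAN)
    },
    "multipliers": [],
}


@pytest.fixture
def frozen_norrisk1():
    return coefficients_from_dict(FROZEN_NORRISK1)


@pytest.fixture
def frozen_norrisk2():
    return coefficients_from_dict(FROZEN_NORRISK2)
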