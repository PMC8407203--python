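"""Comparison pipeline: tables, deltas, Venn, McNemar, characteristics."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from norrisk.cohort import (
    MAN,
    REGIME_2009,
    REGIME_2017,
    WOMAN,
    cohort_to_frame,
)
from norrisk.compare import (
    CellStats,
    CohortTable,
    build_eligibility_table,
    classify_cohort,
    mcnemar_from_counts,
    mcnemar_test,
    percentage_point_delta,
    round_half_up,
    scaled_impact,
    sex_difference_tests,
    summarize_characteristics,
    venn_partition,
)
from norrisk.rules import default_policy
from conftest import make_profile


class TestEligibilityTable:
    def test_hand_built_cohort_matches_hand_tally(self, frozen_norrisk1):
        """10 engineered records under the 2009 regime, tallied by hand.

        With the frozen test config, a 52-year-old non-smoking man with
        sbp 110 and total cholesterol 4.0 has lp = 0.2 - 0.2 - 0.3 and
        scores 100*(1-0.95^exp(-0.3)) ~ 3.7%, below the 5% threshold for
        ages 50-59. Raising sbp to 150 (h1) or 165 (h4) pushes the score
        above threshold; diastolic pressure is not a score predictor, so
        dbp >= 100 (h3, h5) triggers the criterion while staying
        score-low.
        """
        low = dict(sex=MAN, age=52.0, sbp=110.0, dbp=70.0, total_chol=4.0,
                   smoking=False, hba1c=5.0, family_history_chd=False)
        cohort = [
            make_profile(id="h1", **{**low, "sbp": 150.0,
                                     "total_chol": 6.0}),   # score high
            make_profile(id="h2", **low),                    # low, nothing
            make_profile(id="h3", **{**low, "dbp": 101.0}),  # low + dbp rule
            make_profile(id="h4", **{**low, "sbp": 165.0}),  # high (and sbp)
            make_profile(id="h5", **{**low, "dbp": 100.0}),  # low + dbp rule
        ] + [make_profile(id=f"h{i}", **low) for i in range(6, 11)]
        policy = default_policy(REGIME_2009)
        results = classify_cohort(cohort, REGIME_2009, policy, frozen_norrisk1)
        table = build_eligibility_table(cohort, REGIME_2009, policy,
                                        results=results)
        cell = table.cell()
        # hand tally: 2 score-high, 2 score-low dbp-criterion, 4 eligible
        assert cell.denominator == 10
        assert cell.counts["score_high"] == 2
        assert cell.counts["dbp_ge_100"] == 2
        assert cell.counts["sbp_ge_160"] == 0  # h4 is score-high, not counted
        assert cell.counts["total_chol_ge_8"] == 0
        assert cell.counts["total_eligible"] == 4
        assert cell.percents["total_eligible"] == 40.0
        by_id = {p.id: r for p, r in zip(cohort, results)}
        assert by_id["h1"].score_high and by_id["h4"].score_high
        assert by_id["h3"].eligible_by_single_factor_only
        assert not by_id["h2"].eligible

    def test_everyone_score_high_zeroes_criterion_rows(self, frozen_norrisk1):
        cohort = [make_profile(id=f"s{i}", sex=MAN, age=52.0, sbp=190.0,
                               dbp=110.0, total_chol=9.0, smoking=True,
                               hba1c=7.0) for i in range(6)]
        table = build_eligibility_table(cohort, REGIME_2009,
                                        coeffs=frozen_norrisk1)
        cell = table.cell()
        assert cell.counts["score_high"] == 6
        assert cell.counts["total_eligible"] == 6
        for row in ("total_chol_ge_8", "sbp_ge_160", "dbp_ge_100"):
            assert cell.counts[row] == 0

    def test_table_counts_reconcile_with_boolean_vectors(self,
                                                         validation_cohort):
        """Independent brute-force pass over the eligibility vectors."""
        policy = default_policy(REGIME_2017)
        results = classify_cohort(validation_cohort, REGIME_2017, policy)
        table = build_eligibility_table(validation_cohort, REGIME_2017,
                                        policy, results=results)
        df = cohort_to_frame(validation_cohort)
        df["score_high"] = [r.score_high for r in results]
        df["eligible"] = [r.eligible for r in results]
        for (group, band), cell in table.cells.items():
            sub = df
            if group != "all":
                sub = sub[sub["sex"] == group]
            if band != "all":
                lo = float(band.split("-")[0])
                hi = float(band.split("-")[1])
                sub = sub[(sub["age"] >= lo) & (sub["age"] < hi + 1)]
            assert cell.denominator == len(sub)
            assert cell.counts["score_high"] == int(sub["score_high"].sum())
            assert cell.counts["total_eligible"] == int(sub["eligible"].sum())
            for row, n in cell.counts.items():
                assert cell.percents[row] == round_half_up(
                    100.0 * n / cell.denominator)

    def test_decomposition_identity(self, validation_cohort):
        for regime in (REGIME_2009, REGIME_2017):
            results = classify_cohort(validation_cohort, regime)
            eligible = sum(r.eligible for r in results)
            high = sum(r.score_high for r in results)
            single_only = sum(r.eligible_by_single_factor_only
                              for r in results)
            assert eligible == high + single_only

    def test_regression_snapshot_on_validation_fixture(self,
                                                       validation_cohort):
        """Frozen outputs of the first verified build on the shipped
        fixture; the 2017 regime identifies more eligible individuals."""
        t09 = build_eligibility_table(validation_cohort, REGIME_2009)
        t17 = build_eligibility_table(validation_cohort, REGIME_2017)
        assert t09.count("score_high") == 55
        assert t09.count("total_eligible") == 68
        assert t09.percent("total_eligible") == 13.6
        assert t17.count("score_high") == 38
        assert t17.count("total_eligible") == 79
        assert t17.percent("total_eligible") == 15.8
        assert t17.percent("total_eligible") > t09.percent("total_eligible")


class TestDeltas:
    def test_identical_tables_give_zero(self, validation_cohort):
        table = build_eligibility_table(validation_cohort, REGIME_2009)
        d = percentage_point_delta(table, table)
        assert d.delta_reported == 0.0
        assert d.delta_unrounded == 0.0

    def test_mismatched_denominators_refused(self):
        a = CohortTable(REGIME_2009, ("total_eligible",), {
            ("all", "all"): CellStats.from_counts(100, {"total_eligible": 10})})
        b = CohortTable(REGIME_2017, ("total_eligible",), {
            ("all", "all"): CellStats.from_counts(99, {"total_eligible": 10})})
        with pytest.raises(Exception):
            percentage_point_delta(a, b)

    def test_scaled_impact_arithmetic(self):
        assert scaled_impact(3.4, 2_100_000) == 71_400
        assert scaled_impact(0.0, 2_100_000) == 0
        assert scaled_impact(13.8, 2_100_000) == 289_800


class TestVenn:
    def test_identical_classifiers(self):
        v = venn_partition([True, False, True], [True, False, True])
        assert (v.only_a, v.only_b, v.both, v.neither) == (0, 0, 2, 1)

    def test_disjoint_classifiers(self):
        v = venn_partition([True, False], [False, True])
        assert v.both == 0

    def test_planted_counts_recovered(self):
        a = [True] * 3 + [False] * 2 + [True] * 5 + [False] * 90
        b = [False] * 3 + [True] * 2 + [True] * 5 + [False] * 90
        v = venn_partition(a, b)
        assert (v.only_a, v.only_b, v.both, v.neither) == (3, 2, 5, 90)
        assert v.n_total == 100
        assert v.percents()["both"] == 5.0

    def test_venn_totals_match_tables(self, validation_cohort):
        r09 = classify_cohort(validation_cohort, REGIME_2009)
        r17 = classify_cohort(validation_cohort, REGIME_2017)
        t09 = build_eligibility_table(validation_cohort, REGIME_2009,
                                      results=r09)
        t17 = build_eligibility_table(validation_cohort, REGIME_2017,
                                      results=r17)
        v = venn_partition([r.eligible for r in r09],
                           [r.eligible for r in r17])
        assert v.only_a + v.both == t09.count("total_eligible")
        assert v.only_b + v.both == t17.count("total_eligible")
        assert v.only_a + v.only_b + v.both + v.neither == len(
            validation_cohort)


class TestMcNemar:
    def test_symmetric_discordance(self):
        r = mcnemar_from_counts(7, 7)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_one_sided_discordance_statistic(self):
        assert mcnemar_from_counts(10, 0).statistic == pytest.approx(10.0)

    def test_exact_binomial_tail(self):
        # two-sided tail of Bin(11, 1/2) at 8, enumerated directly
        tail = sum(math.comb(11, k) for k in (8, 9, 10, 11)) / 2 ** 11
        r = mcnemar_from_counts(8, 3)
        assert r.p_value == pytest.approx(2 * tail)
        assert "exact" in r.method

    def test_no_discordance_degenerate(self):
        r = mcnemar_test([True, False], [True, False])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_matches_statsmodels_on_both_branches(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in ((8, 3), (2, 9), (30, 12), (40, 40)):
            mine = mcnemar_from_counts(b, c)
            exact = (b + c) < 25
            ref = sm_mcnemar([[0, b], [c, 0]], exact=exact, correction=False)
            assert mine.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)
            if not exact:
                assert mine.statistic == pytest.approx(float(ref.statistic),
                                                       rel=1e-10)


class TestSexDifferences:
    def test_identical_distributions_give_zero_t(self):
        cohort = ([make_profile(id=f"w{i}", sex=WOMAN, total_chol=5.0 + i)
                   for i in range(5)]
                  + [make_profile(id=f"m{i}", sex=MAN, total_chol=5.0 + i)
                     for i in range(5)])
        r = sex_difference_tests(cohort, "total_chol")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert "Welch" in r.method

    def test_balanced_2x2_gives_zero_chi2(self):
        cohort = ([make_profile(id=f"w{i}", sex=WOMAN, smoking=i < 10)
                   for i in range(20)]
                  + [make_profile(id=f"m{i}", sex=MAN, smoking=i < 10)
                     for i in range(20)])
        r = sex_difference_tests(cohort, "smoking")
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_chi2_equals_hand_computed_sum(self):
        # women 30/100 smokers, men 10/100: chi2 = sum (O-E)^2/E = 12.5
        cohort = ([make_profile(id=f"w{i}", sex=WOMAN, smoking=i < 30)
                   for i in range(100)]
                  + [make_profile(id=f"m{i}", sex=MAN, smoking=i < 10)
                     for i in range(100)])
        r = sex_difference_tests(cohort, "smoking")
        assert r.statistic == pytest.approx(12.5)
        assert r.p_value == pytest.approx(float(stats.chi2.sf(12.5, 1)))

    def test_empty_sex_stratum_errors(self):
        with pytest.raises(Exception):
            sex_difference_tests([make_profile(sex=MAN)], "total_chol")


class TestCharacteristics:
    def test_single_record_mean_without_sd(self):
        summary = summarize_characteristics([make_profile(total_chol=5.2)])
        row = summary[(summary["group"] == "all")
                      & (summary["variable"] == "total_chol")].iloc[0]
        assert row["mean"] == pytest.approx(5.2)
        assert row["sd"] is None or (isinstance(row["sd"], float)
                                     and math.isnan(row["sd"]))

    def test_abdominal_obesity_cutoffs(self):
        df = cohort_to_frame([
            make_profile(id="w1", sex=WOMAN), make_profile(id="w2", sex=WOMAN),
            make_profile(id="m1", sex=MAN)])
        df["waist"] = [88.0, 87.9, 101.9]
        summary = summarize_characteristics(df)
        row = summary[(summary["group"] == "all")
                      & (summary["variable"] == "abdominal_obesity")].iloc[0]
        assert row["count"] == 1  # only the 88.0 cm woman

    def test_bmi_categories_only_when_present(self, validation_cohort):
        summary = summarize_characteristics(validation_cohort)
        assert "bmi_normal" not in set(summary["variable"])
        df = cohort_to_frame(validation_cohort[:10])
        df["bmi"] = [22.0, 24.9, 25.0, 27.5, 29.9, 30.0, 31.0, 24.0, 26.0,
                     33.0]
        summary = summarize_characteristics(df)
        cats = summary[(summary["group"] == "all")
                       & (summary["variable"].str.startswith("bmi_"))]
        counts = dict(zip(cats["variable"], cats["count"]))
        assert counts == {"bmi_normal": 3, "bmi_overweight": 4, "bmi_obese": 3}

    def test_fixture_means_near_generator_targets(self, validation_cohort):
        summary = summarize_characteristics(validation_cohort)
        row = summary[(summary["group"] == "woman") & (summary["band"] == "all")
                      & (summary["variable"] == "sbp")].iloc[0]
        # women-overall systolic BP target aggregates to ~123.5 mm Hg
        assert row["mean"] == pytest.approx(123.5, abs=3.0)


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (15.55, 15.6), (15.549, 15.5), (0.05, 0.1), (2.25, 2.3),
        (-1.25, -1.3),
    ])
    def test_half_up_at_one_decimal(self, value, expected):
        assert round_half_up(value) == expected
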