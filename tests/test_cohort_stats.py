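import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thoravol.cohort_stats import (
    bland_altman,
    categorical_test,
    choose_test,
    compare_groups,
    fit_infarct_regression,
)


class TestChooseTest:
    def test_normal_data_mostly_selects_t(self):
        """Shapiro at alpha=0.05 passes both groups ~0.95^2 = 90% of the time."""
        rng = np.random.default_rng(0)
        picks = [choose_test([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
                 for _ in range(200)]
        rate = picks.count("t") / len(picks)
        assert 0.84 <= rate <= 0.96

    def test_skewed_data_selects_rank_test(self):
        rng = np.random.default_rng(1)
        assert choose_test([rng.exponential(1, 200),
                            rng.exponential(1, 200)]) == "mann-whitney"

    def test_arity_rule_for_four_normal_groups(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 100) for _ in range(4)]
        assert choose_test(groups) in ("anova", "kruskal-wallis")
        # with these draws all four pass normality
        assert choose_test(groups) == "anova"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            choose_test([[1.0, 2.0], [1.0, 2.0, 3.0]])


def two_group_frame(a, b):
    return pd.DataFrame({"group": ["A"] * len(a) + ["B"] * len(b),
                         "v": list(a) + list(b)})


class TestCompareGroups:
    def test_identical_groups_no_effect(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 2, 30)
        res = compare_groups(two_group_frame(vals, vals), "v")
        if res.test_name == "mann-whitney":
            assert res.p_value == pytest.approx(1.0, abs=0.01)
        else:
            assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_separated_groups_hand_example(self):
        res = compare_groups(two_group_frame([1, 2, 3], [101, 102, 103]), "v")
        assert res.test_name == "t"
        assert res.p_value < 0.001
        assert abs(res.statistic) > 100  # pooled/Welch t = -122.47 here

    def test_degenerate_zero_variance_everywhere(self):
        res = compare_groups(two_group_frame([5, 5, 5], [5, 5, 5]), "v")
        assert res.degenerate
        assert math.isnan(res.p_value)

    def test_four_group_anova_on_table_cohort(self, cohort_default):
        res = compare_groups(cohort_default, "indexed_itfv")
        assert res.test_name in ("anova", "kruskal-wallis")
        assert len(res.groups) == 4
        assert 0.0 <= res.p_value <= 1.0

    def test_missing_values_dropped(self, cohort_default):
        res = compare_groups(cohort_default.dropna(subset=["scar_pct"]),
                             "scar_pct")
        assert {g.label for g in res.groups} == {"MetS-/MI+", "MetS+/MI+"}


class TestCategorical:
    def test_perfect_independence(self):
        name, stat, p = categorical_test(np.array([[10, 10], [10, 10]]))
        assert p == pytest.approx(1.0)

    def test_small_expected_cells_use_fisher(self):
        name, stat, p = categorical_test(np.array([[1, 9], [8, 2]]))
        assert name == "fisher"

    def test_large_balanced_table_uses_chi_square(self):
        name, stat, p = categorical_test(np.array([[50, 50], [50, 50]]))
        assert name == "chi-square"
        assert stat == pytest.approx(0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            categorical_test(np.zeros((2, 2), int))


class TestRegression:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(4)
        itfv = rng.uniform(10, 50, 60)
        df = pd.DataFrame({"scar_pct": 2.0 + 0.8 * itfv,
                           "indexed_itfv": itfv,
                           "age": rng.uniform(40, 80, 60)})
        res = fit_infarct_regression(df, predictors=("indexed_itfv", "age"))
        assert res.coefficients["indexed_itfv"] == pytest.approx(0.8, abs=1e-9)
        assert res.coefficients["age"] == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_duplicated_predictor_excluded(self):
        rng = np.random.default_rng(5)
        itfv = rng.uniform(10, 50, 40)
        df = pd.DataFrame({"scar_pct": 5 + 0.8 * itfv + rng.normal(0, 2, 40),
                           "indexed_itfv": itfv,
                           "itfv_copy": itfv})
        res = fit_infarct_regression(df, predictors=("indexed_itfv", "itfv_copy"))
        assert res.included == ["indexed_itfv"]
        (name, partner, r), = res.excluded
        assert name == "itfv_copy" and partner == "indexed_itfv"
        assert r == pytest.approx(1.0)

    def test_waist_collinearity_screened_on_cohort(self, cohort_default):
        res = fit_infarct_regression(
            cohort_default, predictors=("indexed_itfv", "waist_cm", "age"))
        assert any(name == "waist_cm" and partner == "indexed_itfv"
                   for name, partner, _ in res.excluded)

    def test_categorical_predictors_encoded(self, cohort_default):
        res = fit_infarct_regression(cohort_default)
        assert any(name.startswith("sex_") for name in res.included)
        assert res.n == cohort_default["scar_pct"].notna().sum()

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"scar_pct": [1.0, 2.0], "indexed_itfv": [1.0, 2.0]})
        with pytest.raises(ValueError, match="n >"):
            fit_infarct_regression(df, predictors=("indexed_itfv",))


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(10, 10), (20, 20), (30, 30)])
        assert res.bias == 0.0
        assert res.lower_limit == res.upper_limit == 0.0
        assert res.pearson_r == 1.0

    def test_hand_worked_three_pairs(self):
        res = bland_altman([(10, 12), (20, 18), (30, 33)])
        assert res.bias == pytest.approx(-1.0)
        assert res.sd_diff == pytest.approx(2.6458, abs=1e-3)
        assert res.lower_limit == pytest.approx(-6.186, abs=0.01)
        assert res.upper_limit == pytest.approx(4.186, abs=0.01)

    def test_constant_offset_direction_convention(self):
        # d = A - B, so B = A + c gives bias exactly -c with zero width
        res = bland_altman([(10, 13), (20, 23), (30, 33)])
        assert res.bias == -3.0
        assert res.upper_limit - res.lower_limit == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2 pairs"):
            bland_altman([(1.0, 2.0)])

    @given(st.lists(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
                    min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_limits_bracket_bias_with_exact_width(self, pairs):
        res = bland_altman(pairs)
        assert res.lower_limit <= res.bias <= res.upper_limit
        width = res.upper_limit - res.lower_limit
        assert width == pytest.approx(2 * 1.96 * res.sd_diff, rel=1e-9, abs=1e-9)


class TestNullCalibration:
    def test_type_one_error_near_nominal(self):
        """All four groups from one normal: rejection rate ~5% at alpha=0.05."""
        rng = np.random.default_rng(6)
        sizes = (16, 32, 30, 32)
        labels = np.repeat([f"g{i}" for i in range(4)], sizes)
        reject = 0
        n_rep = 400
        for _ in range(n_rep):
            df = pd.DataFrame({"group": labels,
                               "v": rng.normal(30, 12, sum(sizes))})
            reject += compare_groups(df, "v").p_value < 0.05
        assert 0.03 <= reject / n_rep <= 0.07

    def test_table_parameterized_means_keep_monotone_order(self):
        """Group means stay in the study's monotone order at n = 400/group."""
        from dataclasses import replace
        from thoravol.synthetic_data import (CohortSpec, DEFAULT_GROUP_PARAMS,
                                             GROUPS, simulate_cohort)
        groups = {label: replace(gp, n=400)
                  for label, gp in DEFAULT_GROUP_PARAMS.items()}
        ordered = 0
        n_rep = 40
        for seed in range(n_rep):
            cohort = simulate_cohort(CohortSpec(groups=groups, seed=seed))
            means = [cohort.loc[cohort.group == g, "indexed_itfv"].mean()
                     for g in GROUPS]
            ordered += all(a < b for a, b in zip(means, means[1:]))
        assert ordered >= 0.95 * n_rep
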