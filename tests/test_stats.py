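"""Statistics engine: primitives, tests and the gated decision tree."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from caspike.exceptions import (
    DegenerateDataError,
    DomainError,
    InvalidParameterError,
    UnsupportedSizeError,
)
from caspike.stats import (
    ContingencyTable,
    SampleGroup,
    anova_tukey,
    choose_and_run,
    fisher_exact,
    fisher_variance_test,
    kruskal_wallis,
    kw_pvalue,
    mann_whitney,
    p_from_W,
    shapiro_wilk,
    student_t_test,
    t_pvalue,
    transform,
    welch_df,
    welch_t_test,
)


class TestTPvalue:
    @pytest.mark.parametrize(
        "t,df,tail,expected",
        [
            (-3.0927, 39, "two", 0.0037),
            (-3.066, 27, "two", 0.0049),
            (2.4153, 99, "two", 0.0176),
            (2.1821, 9, "one", 0.0285),
            (0.9612, 22, "one", 0.1735),
        ],
    )
    def test_reference_values(self, t, df, tail, expected):
        # tolerance: one unit in the last printed decimal place
        assert t_pvalue(t, df, tail) == pytest.approx(expected, abs=1e-4)

    def test_zero_statistic(self):
        assert t_pvalue(0.0, 17, "two") == 1.0

    def test_invalid_df(self):
        with pytest.raises(InvalidParameterError):
            t_pvalue(1.0, 0, "two")

    @given(df=st.floats(1, 200), t1=st.floats(0, 5), dt=st.floats(0.01, 5))
    @settings(max_examples=100, derandomize=True)
    def test_p_strictly_decreasing_in_abs_statistic(self, df, t1, dt):
        assert t_pvalue(t1 + dt, df, "two") < t_pvalue(t1, df, "two")


class TestWelch:
    def test_equal_n_equal_s_reduces_to_pooled(self):
        assert welch_df(12, 3.0, 12, 3.0) == pytest.approx(2 * 11)

    def test_one_variance_vanishing_limit(self):
        df = welch_df(7, 2.0, 10000, 1e-9)
        assert df == pytest.approx(6, rel=1e-3)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_df(5, 0.0, 5, 0.0)

    def test_reconstructed_pair_reproduces_p(self):
        # choose variances with n1=7, n2=8 so the Welch df equals 8.2905,
        # then the printed t statistic must give the printed p
        from scipy.optimize import brentq

        n1, n2 = 7, 8

        def df_of(c):  # c = (s2/s1)^2 scale on the variance ratio v2/v1
            v1, v2 = 1.0 / n1, c / n2
            return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))

        c = brentq(lambda c: df_of(c) - 8.2905, 1e-6, 1.0)
        s1 = 1.0
        s2 = math.sqrt(c)
        df = welch_df(n1, s1, n2, s2)
        assert df == pytest.approx(8.2905, abs=1e-3)
        assert t_pvalue(4.8433, df, "two") == pytest.approx(0.0012, abs=5e-5)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "W,n1,n2,expected",
        [
            (91032, 371, 440, 0.0046),
            (9944, 160, 156, 0.0018),
            (1724, 51, 50, 0.0023),
        ],
    )
    def test_normal_approx_reference_values(self, W, n1, n2, expected):
        assert p_from_W(W, n1, n2) == pytest.approx(expected, abs=5e-5)

    def test_centre_gives_p_one(self):
        assert p_from_W(12 * 10 / 2, 12, 10, continuity=False) == pytest.approx(1.0)

    def test_tiny_exact_enumeration(self):
        # n1=n2=2, first group entirely below: U=0, 6 arrangements, p = 2/6
        assert p_from_W(0, 2, 2, method="exact") == pytest.approx(1 / 3)
        x = SampleGroup("x", [1.0, 2.0])
        y = SampleGroup("y", [3.0, 4.0])
        res = mann_whitney(x, y)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1 / 3)
        assert res.audit["method"] == "exact"

    def test_exact_matches_brute_force_enumeration(self):
        # all group sizes with n1+n2 <= 10: DP distribution == labeling enumeration
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                N = n1 + n2
                counts = np.zeros(n1 * n2 + 1)
                for subset in itertools.combinations(range(1, N + 1), n1):
                    counts[sum(subset) - n1 * (n1 + 1) // 2] += 1
                total = counts.sum()
                for u in range(n1 * n2 + 1):
                    p_le = counts[: u + 1].sum() / total
                    p_ge = counts[u:].sum() / total
                    expected = min(1.0, 2 * min(p_le, p_ge))
                    assert p_from_W(u, n1, n2, method="exact") == pytest.approx(expected)

    def test_normal_approx_converges_to_exact(self):
        # at n1 = n2 = 20 with no ties the approximation sits within 5% of the
        # exact p away from the extreme tails
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = SampleGroup("x", rng.normal(0, 1, 20))
            y = SampleGroup("y", rng.normal(0, 1, 20))
            exact = mann_whitney(x, y, method="exact").p
            approx = mann_whitney(x, y, method="normal_approx").p
            assert approx == pytest.approx(exact, rel=0.05)

    def test_ties_fall_back_with_warning(self):
        x = SampleGroup("x", [1, 2, 2, 3])
        y = SampleGroup("y", [2, 4, 5])
        res = mann_whitney(x, y, method="exact")
        assert res.audit["method"] == "normal_approx"
        assert any("ties" in w for w in res.warnings)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 9)
            res = mann_whitney(SampleGroup("x", x), SampleGroup("y", y))
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.statistic == ref.statistic
            assert res.p == pytest.approx(ref.pvalue)


class TestKruskal:
    def test_reference_value(self):
        assert kw_pvalue(55.44, 3) == pytest.approx(9.17e-13, rel=5e-3)

    def test_zero_statistic(self):
        assert kw_pvalue(0.0, 4) == 1.0

    def test_identical_data_warns(self):
        res = kruskal_wallis([SampleGroup("a", [1, 1]), SampleGroup("b", [1, 1])])
        assert res.p == 1.0 and res.warnings

    def test_permutation_oracle(self):
        # K on random 3-way splits of one sample follows chi-square(2)
        rng = np.random.default_rng(42)
        pooled = rng.normal(0, 1, 30)
        ks = []
        for _ in range(2000):
            perm = rng.permutation(pooled)
            groups = [SampleGroup("a", perm[:10]), SampleGroup("b", perm[10:20]),
                      SampleGroup("c", perm[20:])]
            ks.append(kruskal_wallis(groups).statistic)
        # compare the simulated upper tail with the chi-square reference
        frac = np.mean(np.asarray(ks) > sps.chi2.ppf(0.95, 2))
        assert frac == pytest.approx(0.05, abs=0.02)


class TestAnovaTukey:
    def _groups(self, rng, means, n=25):
        return [SampleGroup(f"g{i}", rng.normal(m, 1, n)) for i, m in enumerate(means)]

    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        groups = [SampleGroup(lab, vals) for lab in "abc"]
        res = anova_tukey(groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert np.all(res.posthoc["p_adj"] > 0.999)
        assert len(set(res.letters.values())) == 1

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(1)
        groups = self._groups(rng, [0, 0, 5])
        res = anova_tukey(groups)
        assert res.df == (2.0, 72.0)
        assert res.letters["g2"] != res.letters["g0"]
        assert res.letters["g0"] == res.letters["g1"]
        assert len(res.posthoc) == 3

    def test_all_identical_undefined(self):
        groups = [SampleGroup(lab, [2.0, 2.0]) for lab in "abc"]
        with pytest.raises(DegenerateDataError):
            anova_tukey(groups)

    def test_tukey_adjusted_p_dominates_unadjusted(self):
        rng = np.random.default_rng(6)
        groups = self._groups(rng, [0, 0.5, 1.0], n=15)
        res = anova_tukey(groups)
        by_label = {g.label: g for g in groups}
        for _, row in res.posthoc.iterrows():
            raw = sps.ttest_ind(by_label[row["group1"]].values,
                                by_label[row["group2"]].values).pvalue
            assert row["p_adj"] >= raw - 1e-12


class TestFisherExact:
    def test_balanced_table(self):
        res = fisher_exact(ContingencyTable(np.array([[5, 5], [5, 5]])))
        assert res.p == 1.0

    def test_enumerated_value(self):
        res = fisher_exact(ContingencyTable(np.array([[3, 1], [1, 3]])))
        assert res.p == pytest.approx(0.4857, abs=5e-5)

    def test_extreme_table_closed_form(self):
        res = fisher_exact(ContingencyTable(np.array([[10, 0], [0, 10]])))
        assert res.p == pytest.approx(2 / math.comb(20, 10))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            ContingencyTable(np.array([[1.5, 2.0], [3.0, 4.0]]))


class TestTransforms:
    def test_boxcox_lambda_one_is_affine_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        res = transform(x, "boxcox", lmbda=1.0)
        np.testing.assert_allclose(res.values, x - 1.0)

    def test_boxcox_lambda_zero_is_log(self):
        x = np.array([1.0, math.e, math.e**2])
        res = transform(x, "boxcox", lmbda=0.0)
        np.testing.assert_allclose(res.values, [0, 1, 2])

    def test_reference_lambda_preserves_ranks(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1.0, 0.8, 60)
        res = transform(x, "boxcox", lmbda=1.353535)
        assert np.array_equal(np.argsort(x), np.argsort(res.values))

    def test_fitted_lambda_reported(self):
        rng = np.random.default_rng(1)
        res = transform(rng.lognormal(0, 0.5, 100), "boxcox")
        assert res.lmbda is not None
        assert "lambda=" in res.label

    def test_domain_error_names_index(self):
        with pytest.raises(DomainError, match="index 1"):
            transform([2.0, 0.0, 3.0], "log10")


class TestShapiro:
    def test_normal_sample_accepted(self):
        rng = np.random.default_rng(2)
        assert shapiro_wilk(rng.normal(0, 1, 50)) > 0.05

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(2)
        assert shapiro_wilk(rng.exponential(1, 50)) < 0.05

    def test_size_and_variance_errors(self):
        with pytest.raises(UnsupportedSizeError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([3.0, 3.0, 3.0])


class TestVarianceGate:
    def test_symmetric_two_tailed(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 20), rng.normal(0, 3, 25)
        f_xy, _, p_xy = fisher_variance_test(x, y)
        f_yx, _, p_yx = fisher_variance_test(y, x)
        assert p_xy == pytest.approx(p_yx)
        assert f_xy == pytest.approx(1 / f_yx)


class TestDecisionTree:
    def test_normal_homoscedastic_dispatches_student(self):
        rng = np.random.default_rng(7)
        groups = [SampleGroup("a", rng.normal(0, 1, 30)),
                  SampleGroup("b", rng.normal(0, 1, 30))]
        res = choose_and_run(groups)
        assert res.test == "student_t"
        assert res.transform == "none"
        assert "shapiro" in res.audit and "variance_gate" in res.audit

    def test_heteroscedastic_dispatches_welch(self):
        rng = np.random.default_rng(8)
        groups = [SampleGroup("a", rng.normal(0, 1, 40)),
                  SampleGroup("b", rng.normal(0, 6, 40))]
        res = choose_and_run(groups)
        assert res.test == "welch_t"

    def test_contaminated_data_dispatches_mann_whitney(self):
        # two-scale mixture, bimodal on every monotone scale: no transform
        # normalises it, so the tree must fall through to the rank test
        rng = np.random.default_rng(9)
        a = np.concatenate([rng.lognormal(0, 0.05, 20), rng.lognormal(7, 0.05, 10)])
        b = np.concatenate([rng.lognormal(0, 0.05, 20), rng.lognormal(7, 0.05, 10)])
        res = choose_and_run([SampleGroup("a", a), SampleGroup("b", b)])
        assert res.test == "mann_whitney"
        assert any("nonparametric" in step for step in res.audit["decision_path"])

    def test_lognormal_recovered_by_log10(self):
        rng = np.random.default_rng(10)
        groups = [SampleGroup("a", rng.lognormal(0, 1, 40)),
                  SampleGroup("b", rng.lognormal(0, 1, 40))]
        res = choose_and_run(groups)
        assert res.test in ("student_t", "welch_t")
        assert res.transform == "log10"

    def test_three_normal_groups_get_anova_with_three_pairs(self):
        rng = np.random.default_rng(11)
        groups = [SampleGroup(lab, rng.normal(0, 1, 20)) for lab in "abc"]
        res = choose_and_run(groups)
        assert res.test == "anova_tukey"
        assert len(res.posthoc) == 3

    def test_small_group_forces_nonparametric(self):
        groups = [SampleGroup("a", [1.0, 2.0]), SampleGroup("b", [3.0, 4.0, 5.0])]
        res = choose_and_run(groups)
        assert res.test == "mann_whitney"
        assert any("n < 3" in w for w in res.warnings)

    def test_one_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            choose_and_run([SampleGroup("a", [1.0, 2.0, 3.0])])

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(20)
        rejections = sum(
            choose_and_run([SampleGroup("a", rng.normal(0, 1, 30)),
                            SampleGroup("b", rng.normal(0, 1, 30))]).p < 0.05
            for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07
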