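import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from selfprior import (
    ancova,
    bonferroni,
    load_table1,
    partial_spearman,
    sign_test_exact,
    spearman,
    t_test,
    table1_summary,
)


class TestTTest:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = t_test(a, list(a))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_one_sample_hand_formula(self):
        res = t_test([1.0, 2.0, 3.0], null_value=0.0)
        assert res.statistic == pytest.approx(2 / (1 / np.sqrt(3)))
        assert res.df == 2

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        res = t_test(a + 100, a)
        assert res.p_value < 1e-6

    def test_pooled_df(self):
        rng = np.random.default_rng(1)
        res = t_test(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert res.df == 38

    def test_paired_equals_one_sample_of_differences(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        res = t_test(a, b, paired=True)
        ref = t_test(a - b, null_value=0.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.p_value)

    def test_zero_variance_equal_means_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_cohens_d_two_sample(self):
        res = t_test([0.0, 2.0], [10.0, 12.0])
        # pooled sd = sqrt(2), d = (1 - 11)/sqrt(2)
        assert res.effect_size == pytest.approx(-10 / np.sqrt(2))


class TestSignTest:
    def test_paper_sign_test(self):
        res = sign_test_exact(29, 40)
        assert round(res.p_value, 3) == 0.006

    def test_center(self):
        assert sign_test_exact(20, 40).p_value == pytest.approx(1.0)

    def test_seventeen_of_twenty(self):
        # 2 * (C(20,17)+C(20,18)+C(20,19)+C(20,20)) / 2^20 = 2*1351/2^20
        assert sign_test_exact(17, 20).p_value == pytest.approx(
            2 * 1351 / 2**20, rel=1e-12
        )

    @given(st.integers(min_value=1, max_value=60), st.data())
    def test_symmetry(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        assert sign_test_exact(k, n).p_value == pytest.approx(
            sign_test_exact(n - k, n).p_value, rel=1e-12
        )

    def test_matches_enumeration_oracle(self):
        from math import comb

        for n, k in [(10, 8), (15, 3), (40, 29), (12, 6)]:
            pmf = [comb(n, i) / 2**n for i in range(n + 1)]
            lower = sum(pmf[: k + 1])
            upper = sum(pmf[k:])
            expected = min(1.0, 2 * min(lower, upper))
            assert sign_test_exact(k, n).p_value == pytest.approx(
                expected, rel=1e-12
            )

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            sign_test_exact(5, 4)


class TestSpearman:
    def test_monotone_increasing(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed(self):
        res = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_rank_formula(self):
        # d = (0, -1, 1, -1, 1), sum d^2 = 4 => rho = 1 - 24/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.statistic == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        base = spearman(x, y).statistic
        assert spearman(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman(x, y**3).statistic == pytest.approx(base)

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialSpearman:
    def test_independent_covariate_keeps_monotone_rho(self):
        rng = np.random.default_rng(4)
        x = np.arange(30.0)
        y = x**2  # perfectly monotone in x
        cov = rng.normal(0, 1, 30)
        res = partial_spearman(x, y, cov)
        assert res.statistic > 0.95

    def test_fully_explained_by_covariate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        cov = rng.normal(0, 1, 40)
        y = cov  # y ranks equal covariate ranks
        res = partial_spearman(x, y, cov)
        assert abs(res.statistic) < 0.2

    def test_matches_precision_matrix_oracle(self):
        # independent route: partial correlation from the inverse
        # correlation matrix of the rank-transformed variables
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 30
            x = rng.normal(0, 1, n)
            y = 0.5 * x + rng.normal(0, 1, n)
            cov = np.column_stack([rng.normal(0, 1, n), x + rng.normal(0, 1, n)])
            ranks = np.column_stack(
                [sps.rankdata(v) for v in (x, y, cov[:, 0], cov[:, 1])]
            )
            R = np.corrcoef(ranks, rowvar=False)
            P = np.linalg.inv(R)
            expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
            res = partial_spearman(x, y, cov)
            assert res.statistic == pytest.approx(expected, rel=1e-10)

    def test_df_reduced_by_covariates(self):
        rng = np.random.default_rng(7)
        res = partial_spearman(
            rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(0, 1, (20, 2))
        )
        assert res.df == 16

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        c = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(x, y, np.column_stack([c, c]))

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match="n >"):
            partial_spearman([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4])


def statsmodels_ancova_oracle(values, groups, covariate):
    """Type-III ANOVA via statsmodels with sum-to-zero coding."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "g": groups, "c": covariate})
    model = smf.ols("y ~ C(g, Sum) * c", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    return table


class TestAncova:
    def simulate(self, seed, group_effect=0.0, n=20):
        rng = np.random.default_rng(seed)
        groups = np.array(["a"] * n + ["b"] * n)
        cov = rng.normal(0, 1, 2 * n)
        y = rng.normal(0, 1, 2 * n) + group_effect * (groups == "a")
        return y, groups, cov

    def test_group_effect_detected_covariate_noise(self):
        y, groups, cov = self.simulate(seed=0, group_effect=3.0, n=50)
        results = {r.test_name: r for r in ancova(y, groups, cov)}
        assert results["ancova_group"].p_value < 1e-6
        assert results["ancova_group:covariate"].p_value > 0.01

    def test_matches_statsmodels_type3(self):
        y, groups, cov = self.simulate(seed=1, group_effect=1.0)
        results = {r.test_name: r for r in ancova(y, groups, cov)}
        table = statsmodels_ancova_oracle(y, groups, cov)
        mapping = {
            "ancova_group": "C(g, Sum)",
            "ancova_covariate": "c",
            "ancova_group:covariate": "C(g, Sum):c",
        }
        for name, sm_name in mapping.items():
            assert results[name].statistic == pytest.approx(
                table.loc[sm_name, "F"], rel=1e-8
            )
            assert results[name].p_value == pytest.approx(
                table.loc[sm_name, "PR(>F)"], rel=1e-8
            )

    def test_symmetric_design_zero_group_f(self):
        # identical value-covariate pairs in both groups => group SS = 0
        cov = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0] * 2)
        y = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5] * 2)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        results = {r.test_name: r for r in ancova(y, groups, cov)}
        assert results["ancova_group"].statistic == pytest.approx(0.0, abs=1e-10)

    def test_null_calibration_permutation(self):
        rng = np.random.default_rng(9)
        y, groups, cov = self.simulate(seed=10, group_effect=0.0)
        ps = []
        for _ in range(500):
            perm = rng.permutation(groups)
            res = {r.test_name: r for r in ancova(y, perm, cov)}
            ps.append(res["ancova_group"].p_value)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_ss_decomposition_balanced_orthogonal(self):
        # orthogonal balanced design: effect SSs plus error SS give total SS
        cov = np.array([-1.0, 1.0] * 6)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 12)
        results = ancova(y, groups, cov)
        X_full = np.column_stack(
            [
                np.ones(12),
                np.where(groups == "a", 1.0, -1.0),
                cov,
                np.where(groups == "a", 1.0, -1.0) * cov,
            ]
        )
        beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        rss = float(np.sum((y - X_full @ beta) ** 2))
        df_err = 12 - 4
        ss_effects = sum(r.statistic * (rss / df_err) for r in results)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        assert ss_effects + rss == pytest.approx(ss_total, rel=1e-8)

    def test_constant_covariate_raises(self):
        y, groups, _ = self.simulate(seed=12)
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova(y, groups, np.ones_like(y))

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="two groups"):
            ancova([1.0, 2.0, 3.0], ["a", "a", "b"], [0.0, 1.0, 2.0])

    def test_classical_eta_variant(self):
        y, groups, cov = self.simulate(seed=13, group_effect=2.0)
        partial = {r.test_name: r for r in ancova(y, groups, cov)}
        classical = {
            r.test_name: r for r in ancova(y, groups, cov, eta_variant="classical")
        }
        assert (
            classical["ancova_group"].effect_size
            <= partial["ancova_group"].effect_size
        )


class TestBonferroni:
    def test_simple(self):
        assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]

    def test_capped(self):
        assert bonferroni([0.5], m=3) == [1.0]

    @settings(max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=8)
    )
    def test_order_preserved(self, ps):
        out = bonferroni(ps, m=len(ps))
        order_in = np.argsort(ps, kind="stable")
        order_out = np.argsort(np.asarray(out)[order_in], kind="stable")
        assert (np.asarray(out)[order_in] == sorted(out)).all()
        assert list(order_out) == sorted(order_out)

    def test_m_too_small(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


class TestTable1:
    def test_fixture_loads_twenty_patients(self):
        table = load_table1()
        assert len(table) == 20

    def test_mean_lde(self):
        summary = table1_summary(load_table1())
        assert summary.loc["lde", "mean_rounded"] == 960

    def test_mean_age(self):
        summary = table1_summary(load_table1())
        assert summary.loc["age", "mean_rounded"] == 68

    def test_mean_updrs_and_acer(self):
        summary = table1_summary(load_table1())
        assert summary.loc["updrs_iii", "mean_rounded"] == 20
        assert summary.loc["acer", "mean_rounded"] == 92

    def test_other_columns(self):
        summary = table1_summary(load_table1())
        assert summary.loc["mmse", "mean_rounded"] == 28
        assert summary.loc["duration_years", "mean_rounded"] == 12
        assert summary.loc["stage", "mean_rounded"] == 2

    def test_ranges(self):
        summary = table1_summary(load_table1())
        assert summary.loc["age", "min"] == 48
        assert summary.loc["age", "max"] == 81

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="lde"):
            table1_summary(load_table1().drop(columns=["lde"]))

    def test_single_row_sd_absent(self):
        summary = table1_summary(load_table1().head(1))
        assert pd.isna(summary.loc["age", "sd"])
        assert summary.loc["age", "mean"] == 74
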