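"""ANCOVA, t-test, chi-square, partial correlation and BH-FDR checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from t2ebm.stats import (
    ancova_compare,
    bh_fdr,
    chi_square_2x2,
    compare_family,
    partial_correlation,
    two_sample_t,
)


def covariates(n, rng):
    return pd.DataFrame(
        {"age": rng.normal(55, 8, n), "sex": rng.integers(0, 2, n),
         "education": rng.normal(12, 3, n)}
    )


class TestAncova:
    def test_reduces_to_oneway_anova_without_covariate_effects(self, rng):
        n = 200
        group = np.repeat(["a", "b"], n // 2)
        y = rng.normal(0, 1, n) + (group == "b") * 0.8
        cov = covariates(n, rng)
        res = ancova_compare(y, group, cov)
        F_anova = stats.f_oneway(y[group == "a"], y[group == "b"]).statistic
        # with null covariates the group F stays close to the one-way F
        assert res.statistic == pytest.approx(F_anova, rel=0.15)
        assert res.p_value < 0.01

    def test_identical_groups_null(self, rng):
        n = 80
        y = np.tile(rng.normal(size=n // 2), 2)
        group = np.repeat(["a", "b"], n // 2)
        cov = pd.concat([covariates(n // 2, rng)] * 2, ignore_index=True)
        res = ancova_compare(y, group, cov)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-8)

    def test_eight_row_fixture_matches_projection_arithmetic(self):
        y = np.array([3.1, 2.8, 4.0, 3.5, 5.2, 4.9, 6.1, 5.7])
        group = np.array(["a"] * 4 + ["b"] * 4)
        cov = pd.DataFrame({"age": [50.0, 52, 54, 56, 51, 53, 55, 57],
                            "sex": [0, 1, 0, 1, 0, 1, 0, 1],
                            "education": [10.0, 16, 9, 13, 12, 11, 15, 8]})
        res = ancova_compare(y, group, cov)
        # explicit partial-F via the two projection fits
        X_full = np.column_stack([np.ones(8), group == "b", cov.to_numpy()])
        X_red = np.column_stack([np.ones(8), cov.to_numpy()])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ((y - X @ beta) ** 2).sum()

        F = (rss(X_red) - rss(X_full)) / (rss(X_full) / (8 - X_full.shape[1]))
        assert res.statistic == pytest.approx(F, rel=1e-8)

    def test_adjusted_means_remove_covariate_imbalance(self, rng):
        n = 400
        group = np.repeat(["a", "b"], n // 2)
        cov = covariates(n, rng)
        cov.loc[group == "b", "age"] += 10          # confounded design
        y = 0.1 * cov["age"].to_numpy() + rng.normal(0, 0.2, n)
        res = ancova_compare(y, group, cov)
        # raw means differ by ~1.0; adjusted means should nearly coincide
        assert abs(res.adjusted_means["a"] - res.adjusted_means["b"]) < 0.15


class TestTwoSampleT:
    def test_identical_samples(self):
        a = np.array([1.0, 2, 3, 4])
        t, df, p = two_sample_t(a, a.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooled_formula_hand_value(self, rng):
        a = rng.normal(1, 1, 100)
        b = rng.normal(0, 1, 100)
        a = (a - a.mean()) / a.std(ddof=1) + 1.0       # exact moments
        b = (b - b.mean()) / b.std(ddof=1)
        t, df, p = two_sample_t(a, b)
        assert df == 198
        assert t == pytest.approx(1 / np.sqrt(2 / 100), abs=1e-9)   # 7.0711

    def test_antisymmetric(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
        t1, _, p1 = two_sample_t(a, b)
        t2, _, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_scipy_agreement(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1, 35)
        t, df, p = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValueError, match="pooled"):
            two_sample_t(np.array([1.0, 1.0]), np.array([2.0, 2.0]))


class TestChiSquare:
    def test_printed_sex_table(self):
        # male/female split 87/32 patients vs 50/37 controls
        chi2, df, p = chi_square_2x2(np.array([[87, 32], [50, 37]]))
        assert chi2 == pytest.approx(5.517, abs=5e-4)
        assert df == 1
        assert p == pytest.approx(0.019, abs=5e-4)

    def test_proportional_table_zero(self):
        chi2, _, p = chi_square_2x2(np.array([[20, 40], [10, 20]]))
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_transpose_invariant(self):
        t = np.array([[12, 5], [8, 19]])
        assert chi_square_2x2(t)[0] == pytest.approx(chi_square_2x2(t.T)[0])

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(np.array([[0, 0], [5, 3]]))


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = partial_correlation(x, y, None)
        assert res.r == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_perfect_dependence(self, rng):
        x = rng.normal(size=40)
        cov = covariates(40, rng)
        res = partial_correlation(x, x.copy(), cov)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_six_row_fixture_matches_residual_oracle(self):
        x = np.array([1.0, 2.1, 2.9, 4.2, 5.1, 5.8])
        y = np.array([2.0, 1.8, 3.5, 3.1, 4.9, 5.2])
        z = np.array([0.5, 1.0, 1.4, 2.1, 2.4, 3.0])
        cov = pd.DataFrame({"z": z})
        res = partial_correlation(x, y, cov)
        X = np.column_stack([np.ones(6), z])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.r == pytest.approx(stats.pearsonr(rx, ry).statistic, abs=1e-10)

    def test_pingouin_cross_check(self, rng):
        """Generic fixture: our residual-based partial r matches pingouin's
        precision-matrix implementation."""
        import pingouin as pg

        n = 80
        cov = covariates(n, rng)
        x = 0.1 * cov["age"].to_numpy() + rng.normal(size=n)
        y = 0.5 * x - 0.2 * cov["education"].to_numpy() + rng.normal(size=n)
        res = partial_correlation(x, y, cov)
        df = cov.copy()
        df["_x"], df["_y"] = x, y
        ref = pg.partial_corr(data=df, x="_x", y="_y",
                              covar=["age", "sex", "education"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_residual_oracle_with_full_covariates(self, rng):
        n = 120
        cov = covariates(n, rng)
        x = 0.05 * cov["age"] + rng.normal(size=n)
        y = -0.1 * cov["education"] + 0.4 * x + rng.normal(size=n)
        res = partial_correlation(x.to_numpy(), y.to_numpy(), cov)
        X = np.column_stack([np.ones(n), cov.to_numpy()])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.r == pytest.approx(stats.pearsonr(rx, ry).statistic, abs=1e-9)


class TestBHFDR:
    def test_step_up_hand_example(self):
        adj = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.random(30)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestFamilies:
    def test_compare_family_shares_fdr(self, rng):
        n = 120
        group = np.repeat(["a", "b"], n // 2)
        cov = covariates(n, rng)
        outcomes = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("wxyz"))
        outcomes["w"] += (group == "b") * 2.0
        results = compare_family(outcomes, group, cov)
        assert len(results) == 4
        raw = np.array([r.p_value for r in results])
        adj = np.array([r.p_fdr for r in results])
        assert np.allclose(adj, bh_fdr(raw))
        assert results[0].p_fdr < 0.01
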