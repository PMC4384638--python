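"""PGLS, contrast regression, Pearson correlation and the t-test kernel."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from phylocomp import (
    PGLS,
    ContrastRegression,
    felsenstein_contrasts,
    fic_regression,
    parse_newick,
    pearson_correlation,
    pgls_fit,
    pgls_residualize,
    student_t_two_tailed_p,
)
from phylocomp.simulate import SimSpec, simulate_bm_traits, simulate_yule_tree
from phylocomp.tree import PhyloCovariance

from conftest import random_tree


# ---------------------------------------------------------------------
# Student-t kernel


class TestStudentT:
    def test_zero_statistic_gives_one(self):
        assert student_t_two_tailed_p(0.0, 7) == 1.0

    def test_df_one_matches_cauchy_closed_form(self):
        for t in (0.5, 1.0, 2.0, 10.0):
            expected = 1.0 - (2.0 / np.pi) * np.arctan(t)
            np.testing.assert_allclose(
                student_t_two_tailed_p(t, 1), expected, rtol=1e-12
            )

    def test_matches_quadrature_to_1e_10(self):
        for df in (1, 2, 5, 11, 30):
            for t in (0.3, 1.7, 3.1, 6.0):
                tail, _ = integrate.quad(
                    lambda u: stats.t.pdf(u, df), abs(t), np.inf
                )
                assert abs(student_t_two_tailed_p(t, df) - 2 * tail) < 1e-10

    def test_strictly_decreasing_in_abs_t(self):
        ps = [student_t_two_tailed_p(t, 11) for t in np.linspace(0, 8, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            student_t_two_tailed_p(1.0, 0)


# ---------------------------------------------------------------------
# Pearson correlation


class TestPearson:
    def test_exact_line_gives_r2_one_p_zero(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 3 * x + 1)
        assert res.r2 == 1.0
        assert res.p == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 25))
        a = pearson_correlation(x, y)
        b = pearson_correlation(5 * x - 2, 0.1 * y + 7)
        np.testing.assert_allclose(a.r, b.r, atol=1e-14)
        np.testing.assert_allclose(a.p, b.p, atol=1e-14)

    def test_log_base_change_leaves_r2_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        life = np.exp(rng.standard_normal(20) + 3)
        a = pearson_correlation(x, np.log10(life))
        b = pearson_correlation(x, np.log(life))
        np.testing.assert_allclose(a.r2, b.r2, atol=1e-14)

    def test_df_conventions(self):
        x = np.arange(14.0)
        rng = np.random.default_rng(2)
        y = x + rng.standard_normal(14)
        assert pearson_correlation(x, y, "paper").df == 11
        assert pearson_correlation(x, y, "standard").df == 12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 30))
        res = pearson_correlation(x, y, "standard")
        ref = stats.pearsonr(x, y)
        np.testing.assert_allclose(res.r, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(res.p, ref.pvalue, rtol=1e-9)


# ---------------------------------------------------------------------
# Contrast regression


class TestContrastRegression:
    def test_exact_proportional_contrasts(self):
        t = random_tree(7, n_min=8, n_max=12)
        rng = np.random.default_rng(7)
        x = {l: float(v) for l, v in zip(t.leaf_labels, rng.standard_normal(t.n_leaves))}
        y = {l: 2.0 * v for l, v in x.items()}
        res = ContrastRegression.from_traits(t, x, y).fit()
        np.testing.assert_allclose(res.slope, 2.0, atol=1e-12)
        assert res.rss < 1e-20
        assert res.pvalue < 1e-10

    def test_df_conventions_at_n14(self):
        t = simulate_yule_tree(14, 1.0, seed=4)
        df = simulate_bm_traits(
            t, SimSpec(rate_matrix=np.array([[1, 0.5], [0.5, 1]]), seed=9)
        )
        xc = felsenstein_contrasts(t, df.iloc[:, 0].to_dict())
        yc = felsenstein_contrasts(t, df.iloc[:, 1].to_dict())
        assert fic_regression(xc, yc, "paper").df_resid == 11
        assert fic_regression(xc, yc, "standard").df_resid == 12

    def test_mismatched_node_order_rejected(self):
        t1 = simulate_yule_tree(8, 1.0, seed=1)
        t2 = simulate_yule_tree(8, 1.0, seed=2)
        trait = {l: 1.0 * i for i, l in enumerate(t1.leaf_labels)}
        xc = felsenstein_contrasts(t1, trait)
        yc = felsenstein_contrasts(t2, trait)
        with pytest.raises(ValueError, match="different trees"):
            fic_regression(xc, yc)

    def test_all_zero_x_contrasts_rejected(self, three_leaf_tree):
        xc = felsenstein_contrasts(three_leaf_tree, {"A": 1.0, "B": 1.0, "C": 1.0})
        yc = felsenstein_contrasts(three_leaf_tree, {"A": 1.0, "B": 2.0, "C": 0.0})
        with pytest.raises(ValueError, match="degenerate"):
            fic_regression(xc, yc)

    def test_positivization_makes_result_sign_invariant(self):
        t = random_tree(11, n_min=6, n_max=10)
        rng = np.random.default_rng(11)
        x = {l: float(v) for l, v in zip(t.leaf_labels, rng.standard_normal(t.n_leaves))}
        y = {l: float(v) for l, v in zip(t.leaf_labels, rng.standard_normal(t.n_leaves))}
        a = ContrastRegression.from_traits(t, x, y).fit()
        # negating a trait flips every contrast; slope flips, |t| identical
        xneg = {l: -v for l, v in x.items()}
        b = ContrastRegression.from_traits(t, xneg, y).fit()
        np.testing.assert_allclose(a.slope, -b.slope, atol=1e-12)
        np.testing.assert_allclose(abs(a.tvalue), abs(b.tvalue), atol=1e-10)


# ---------------------------------------------------------------------
# PGLS


def brute_force_gls(y, X, V, df):
    """Oracle: explicit inversion of V, no factorization shortcuts."""
    Vi = np.linalg.inv(V)
    A = np.linalg.inv(X.T @ Vi @ X)
    beta = A @ X.T @ Vi @ y
    resid = y - X @ beta
    rss = resid @ Vi @ resid
    bse = np.sqrt(np.diag(A) * rss / df)
    return beta, bse


class TestPGLS:
    def _sim(self, seed, n=12, lam=1.0, rho=0.6):
        t = simulate_yule_tree(n, 1.0, seed=seed)
        df = simulate_bm_traits(
            t,
            SimSpec(
                n_taxa=n,
                rate_matrix=np.array([[1.0, rho], [rho, 1.0]]),
                lambda_true=lam,
                seed=seed + 1,
            ),
        )
        return t, df.iloc[:, 0], df.iloc[:, 1]

    def test_identity_covariance_equals_ols(self):
        t, x, y = self._sim(21)
        V = PhyloCovariance(taxa=list(x.index), matrix=np.eye(len(x)))
        fit = pgls_fit(y, x.to_frame("x"), V, lam=1.0)
        ols = sm.OLS(y.values, sm.add_constant(x.values)).fit()
        np.testing.assert_allclose(fit.params.values, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.bse.values, ols.bse, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues.values, ols.pvalues, atol=1e-10)

    def test_scaled_identity_equals_ols_for_any_scale(self):
        t, x, y = self._sim(22)
        for c in (0.1, 3.7):
            V = PhyloCovariance(taxa=list(x.index), matrix=c * np.eye(len(x)))
            fit = pgls_fit(y, x.to_frame("x"), V, lam=1.0)
            ols = sm.OLS(y.values, sm.add_constant(x.values)).fit()
            np.testing.assert_allclose(fit.params.values, ols.params, atol=1e-10)
            np.testing.assert_allclose(fit.bse.values, ols.bse, atol=1e-10)

    def test_lambda_zero_on_ultrametric_equals_ols(self):
        t, x, y = self._sim(23)
        assert t.is_ultrametric()
        fit = pgls_fit(y, x.to_frame("x"), t.vcv(), lam=0.0)
        ols = sm.OLS(y.values, sm.add_constant(x.values)).fit()
        np.testing.assert_allclose(fit.params.values, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.bse.values, ols.bse, atol=1e-10)

    @pytest.mark.parametrize("lam", [0.0, 0.35, 1.0])
    def test_matches_explicit_inverse_oracle(self, lam):
        for seed in range(30, 36):
            t, x, y = self._sim(seed, n=int(4 + seed % 9))
            model = PGLS(y, x.to_frame("x"), t.vcv())
            fit = model.fit(lam=lam)
            beta, bse = brute_force_gls(
                model.endog, model.exog, t.vcv().transform(lam).matrix, fit.df_resid
            )
            np.testing.assert_allclose(fit.params.values, beta, atol=1e-9)
            np.testing.assert_allclose(fit.bse.values, bse, atol=1e-9)

    def test_matches_statsmodels_gls(self):
        t, x, y = self._sim(40, n=14)
        V = t.vcv().transform(1.0).matrix
        fit = pgls_fit(y, x.to_frame("x"), t.vcv(), lam=1.0, df_convention="standard")
        ref = sm.GLS(y.values, sm.add_constant(x.values), sigma=V).fit()
        np.testing.assert_allclose(fit.params.values, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.bse.values, ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues.values, ref.pvalues, atol=1e-9)

    def test_slope_identity_with_contrast_regression(self):
        for seed in range(50, 60):
            t, x, y = self._sim(seed, n=int(5 + seed % 16))
            pg = pgls_fit(y, x.to_frame("x"), t.vcv(), lam=1.0)
            cr = ContrastRegression.from_traits(t, x.to_dict(), y.to_dict()).fit()
            np.testing.assert_allclose(pg.params["x"], cr.slope, atol=1e-8)

    def test_singular_design_named(self):
        t, x, y = self._sim(61)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=x.index)
        with pytest.raises(ValueError, match="singular"):
            pgls_fit(y, X, t.vcv())

    def test_taxa_mismatch_rejected(self):
        t, x, y = self._sim(62)
        bad = y.copy()
        bad.index = [f"zz_{i}" for i in range(len(bad))]
        with pytest.raises(ValueError, match="taxa"):
            pgls_fit(bad, x.to_frame("x"), t.vcv())

    def test_t_equals_coef_over_se_and_p_in_range(self):
        t, x, y = self._sim(63)
        fit = pgls_fit(y, x.to_frame("x"), t.vcv(), lam=1.0)
        np.testing.assert_allclose(
            fit.tvalues.values, fit.params.values / fit.bse.values, rtol=1e-12
        )
        assert ((fit.pvalues >= 0) & (fit.pvalues <= 1)).all()

    def test_whitened_residuals_orthogonal_to_whitened_design(self):
        t, x, y = self._sim(64)
        model = PGLS(y, x.to_frame("x"), t.vcv())
        fit = model.fit(lam=0.7)
        V = t.vcv().transform(0.7).matrix
        L = np.linalg.cholesky(V)
        from scipy.linalg import solve_triangular

        rw = solve_triangular(L, fit.resid.values, lower=True)
        Xw = solve_triangular(L, model.exog, lower=True)
        np.testing.assert_allclose(Xw.T @ rw, 0.0, atol=1e-9)

    def test_summary_mentions_lambda_and_coefficients(self):
        t, x, y = self._sim(65)
        s = pgls_fit(y, x.to_frame("x"), t.vcv(), lam=1.0).summary()
        assert "lambda" in s and "coef" in s and "x" in s


# ---------------------------------------------------------------------
# Lambda profile


class TestLambdaML:
    def test_profile_maximum_dominates_endpoints(self):
        t = simulate_yule_tree(40, 1.0, seed=70)
        df = simulate_bm_traits(
            t,
            SimSpec(
                n_taxa=40,
                rate_matrix=np.array([[1.0, 0.6], [0.6, 1.0]]),
                lambda_true=0.6,
                seed=71,
            ),
        )
        model = PGLS(df.iloc[:, 1], df.iloc[:, [0]], t.vcv())
        prof = model.profile_lambda()
        from phylocomp.models import _profile_llf

        ll_hat = _profile_llf(model.endog, model.exog, model._v_at(prof.lambda_hat))
        assert ll_hat >= prof.log_likelihoods[0] - 1e-9
        assert ll_hat >= prof.log_likelihoods[-1] - 1e-9

    def test_boundaries_reported_exactly(self):
        t = simulate_yule_tree(30, 1.0, seed=72)
        # pure BM signal: lambda_hat should usually hit the 1.0 boundary
        df = simulate_bm_traits(t, SimSpec(n_taxa=30, seed=73))
        model = PGLS(df.iloc[:, 1], df.iloc[:, [0]], t.vcv())
        lam = model.profile_lambda().lambda_hat
        assert lam in (0.0, 1.0) or 0.0 < lam < 1.0  # boundary values are exact

    def test_star_tree_flags_flat_likelihood(self):
        taxa = [f"t{i}" for i in range(8)]
        V = PhyloCovariance(taxa=taxa, matrix=np.eye(8))
        rng = np.random.default_rng(74)
        y = pd.Series(rng.standard_normal(8), index=taxa)
        x = pd.DataFrame({"x": rng.standard_normal(8)}, index=taxa)
        prof = PGLS(y, x, V).profile_lambda()
        assert prof.flat
        assert np.isnan(prof.lambda_hat)
        with pytest.raises(ValueError, match="star tree"):
            PGLS(y, x, V).fit(lam="ml")


# ---------------------------------------------------------------------
# Residualization


class TestResidualize:
    def test_identity_covariance_uncorrelated_covariate_centers(self):
        taxa = [f"t{i}" for i in range(40)]
        rng = np.random.default_rng(80)
        trait = pd.Series(rng.standard_normal(40), index=taxa)
        cov = pd.Series(rng.standard_normal(40), index=taxa, name="c")
        V = PhyloCovariance(taxa=taxa, matrix=np.eye(40))
        res = pgls_residualize(trait, cov.to_frame(), V, lam=1.0)
        # residuals equal centered trait up to the (small) fitted slope term
        fitted_slope_part = res - (trait - trait.mean())
        assert np.abs(fitted_slope_part).max() < np.abs(trait).max()
        np.testing.assert_allclose(res.mean(), 0.0, atol=1e-10)

    def test_recovers_known_partial_correlation(self):
        # x and y share a confounder z plus a direct x -> y link; the
        # residual-residual correlation after removing z has a closed form
        rng = np.random.default_rng(81)
        n = 2000
        taxa = [f"t{i}" for i in range(n)]
        z = rng.standard_normal(n)
        e_x = rng.standard_normal(n)
        e_y = rng.standard_normal(n)
        x = 0.8 * z + 0.6 * e_x
        y = 0.8 * z + 0.5 * x + 0.5 * e_y
        # residual(x|z) = 0.6 e_x; residual(y|z) = 0.3 e_x + 0.5 e_y
        expected = 0.3 / np.sqrt(0.09 + 0.25)
        xs = pd.Series(x, index=taxa)
        ys = pd.Series(y, index=taxa)
        zs = pd.DataFrame({"z": z}, index=taxa)
        V = PhyloCovariance(taxa=taxa, matrix=np.eye(n))
        rx = pgls_residualize(xs, zs, V)
        ry = pgls_residualize(ys, zs, V)
        got = np.corrcoef(rx.loc[taxa], ry.loc[taxa])[0, 1]
        assert abs(got - expected) < 0.05
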