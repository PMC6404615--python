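import numpy as np
import pytest
from scipy import stats

from hetblup import (
    bic_compare,
    build_mean_structure,
    lrt,
    marker_kernel,
    predict_blup,
    reml_fit,
)
from hetblup.mixedmodel import NonIdentifiableWarning


def dense_reml_loglik(y, Q, C, s2u, s2e):
    """Brute-force restricted log-likelihood from the textbook dense formula.

    Deliberately independent of the eigen-profile path: builds V, inverts it,
    and assembles log|V| + log|Q'V^-1 Q| + y'Py directly.
    """
    n, p = Q.shape
    V = s2u * C + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    QVQ = Q.T @ Vi @ Q
    Pmat = Vi - Vi @ Q @ np.linalg.inv(QVQ) @ Q.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldQVQ = np.linalg.slogdet(QVQ)
    _, ldQQ = np.linalg.slogdet(Q.T @ Q)
    return float(
        -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldQVQ + y @ Pmat @ y)
        + 0.5 * ldQQ
    )


def random_instance(seed, n=30, m=60, p=2):
    rng = np.random.default_rng(seed)
    Q = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    X = rng.normal(size=(n, m))
    C = X @ X.T
    u = rng.multivariate_normal(np.zeros(n), C / m)
    y = Q @ rng.normal(size=p) + u + rng.normal(size=n)
    return y, Q, C


class TestMeanStructure:
    def test_intercept_is_column_of_ones(self):
        ms = build_mean_structure("intercept", n=5)
        np.testing.assert_array_equal(ms.Q, np.ones((5, 1)))

    def test_pca_prepends_intercept(self, small_structure):
        _, _, P = small_structure
        ms = build_mean_structure("pca", P=P)
        assert ms.Q.shape == (P.scores.shape[0], 5)
        np.testing.assert_array_equal(ms.Q[:, 0], 1.0)
        np.testing.assert_array_equal(ms.Q[:, 1:], P.scores)

    def test_group_one_hot_without_intercept(self, toy_metadata):
        ms = build_mean_structure("group", meta=toy_metadata)
        assert ms.Q.shape == (4, 2)
        np.testing.assert_array_equal(ms.Q.sum(axis=1), 1.0)

    def test_panel_structure(self, toy_metadata):
        ms = build_mean_structure("panel", meta=toy_metadata)
        assert ms.Q.shape == (4, 2)


class TestRemlFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_formula_oracle(self, seed):
        y, Q, C = random_instance(seed)
        fit = reml_fit(y, Q, C)
        oracle = dense_reml_loglik(y, Q, C, fit.sigma2_u, fit.sigma2_e)
        assert fit.reml_loglik == pytest.approx(oracle, abs=1e-6)

    def test_invariant_to_fixed_effect_translation(self):
        y, Q, C = random_instance(7)
        fit = reml_fit(y, Q, C)
        shifted = reml_fit(y + Q @ np.array([3.0, -2.0]), Q, C)
        assert shifted.sigma2_u == pytest.approx(fit.sigma2_u, abs=1e-8)
        assert shifted.sigma2_e == pytest.approx(fit.sigma2_e, abs=1e-8)
        assert shifted.reml_loglik == pytest.approx(fit.reml_loglik, abs=1e-8)

    def test_optimum_beats_nearby_ratios(self):
        y, Q, C = random_instance(3)
        fit = reml_fit(y, Q, C)
        from hetblup.mixedmodel import reml_loglik_at

        for factor in (0.5, 0.9, 1.1, 2.0):
            assert fit.reml_loglik >= reml_loglik_at(y, Q, C, fit.ratio * factor) - 1e-8

    def test_heritability_recovery(self):
        """Variance-ratio estimates recover a true heritability of 0.5."""
        rng = np.random.default_rng(42)
        n, m = 300, 1000
        ests = []
        for _ in range(30):
            X = rng.normal(size=(n, m))
            C = X @ X.T / m
            u = X @ rng.normal(scale=np.sqrt(1.0 / m), size=m)
            y = u + rng.normal(size=n)
            fit = reml_fit(y, np.ones((n, 1)), C)
            ests.append(fit.sigma2_u / (fit.sigma2_u + fit.sigma2_e))
        assert abs(np.mean(ests) - 0.5) < 0.05

    def test_constant_y_rejected(self):
        _, Q, C = random_instance(0)
        with pytest.raises(ValueError, match="constant"):
            reml_fit(np.ones(30), Q, C)

    def test_identity_kernel_warns_nonidentifiable(self):
        rng = np.random.default_rng(1)
        with pytest.warns(NonIdentifiableWarning):
            reml_fit(rng.normal(size=25), np.ones((25, 1)), np.eye(25))


class TestPredictBlup:
    def test_zero_genetic_variance_predicts_mean(self):
        y, Q, C = random_instance(11)
        fit = reml_fit(y, Q, C)
        fit_no_u = type(fit)(
            alpha_hat=fit.alpha_hat, sigma2_u=0.0, sigma2_e=1.0,
            reml_loglik=fit.reml_loglik, blups=fit.blups, kernel_ref="x",
            y=y[:20], Q=Q[:20],
        )
        pred = predict_blup(fit_no_u, C, Q, np.arange(20), np.arange(20, 30))
        np.testing.assert_allclose(pred, Q[20:] @ fit.alpha_hat)

    def test_duplicate_genotype_interpolates_in_noiseless_limit(self):
        rng = np.random.default_rng(9)
        n, m = 40, 120
        X = rng.normal(size=(n, m))
        X[-1] = X[0]  # TS individual duplicates a CS genotype
        C = X @ X.T
        beta = rng.normal(size=m) / np.sqrt(m)
        y = X @ beta  # no residual noise
        cs, ts = np.arange(n - 1), np.array([n - 1])
        fit = reml_fit(y[cs], np.ones((n - 1, 1)), C[np.ix_(cs, cs)])
        # fitted value for the duplicated CS individual
        fitted_cs = fit.alpha_hat[0] + fit.blups[0]
        pred = predict_blup(fit, C, np.ones((n, 1)), cs, ts)
        assert pred[0] == pytest.approx(fitted_cs, abs=1e-4)

    def test_equals_ridge_regression(self):
        """GBLUP with C = XX' predicts exactly like ridge regression with
        penalty sigma2_e / sigma2_u."""
        rng = np.random.default_rng(21)
        n, m = 50, 200
        X = rng.normal(size=(n, m))
        Xc = X - X.mean(axis=0)
        C = Xc @ Xc.T
        y = Xc @ rng.normal(size=m) / np.sqrt(m) + rng.normal(size=n)
        cs, ts = np.arange(40), np.arange(40, 50)
        fit = reml_fit(y[cs], np.ones((40, 1)), C[np.ix_(cs, cs)])
        pred = predict_blup(fit, C, np.ones((n, 1)), cs, ts)
        lam = fit.sigma2_e / fit.sigma2_u
        Xcs, Xts = Xc[cs], Xc[ts]
        resid = y[cs] - fit.alpha_hat[0]
        beta_rr = np.linalg.solve(Xcs.T @ Xcs + lam * np.eye(m), Xcs.T @ resid)
        np.testing.assert_allclose(pred, fit.alpha_hat[0] + Xts @ beta_rr, atol=1e-6)

    def test_overlapping_sets_rejected(self):
        y, Q, C = random_instance(2)
        fit = reml_fit(y, Q, C)
        with pytest.raises(ValueError, match="overlap"):
            predict_blup(fit, C, Q, np.arange(20), np.arange(19, 30))


class TestModelComparison:
    def _fits(self, ll0, ll1):
        y, Q, C = random_instance(1)
        fit = reml_fit(y, Q, C)
        f0 = type(fit)(**{**vars(fit), "reml_loglik": ll0})
        f1 = type(fit)(**{**vars(fit), "reml_loglik": ll1})
        return f0, f1

    def test_equal_likelihoods_give_p_one(self):
        f0, f1 = self._fits(-100.0, -100.0)
        stat, p = lrt(f0, f1, df=1)
        assert stat == 0.0 and p == 1.0

    def test_reference_statistics_map_to_p_values(self):
        """Reference chi-square mappings: 15.89 (1 df) -> 6.7e-5,
        42.76 (2 df) -> 5.2e-10, 5.72 (1 df) -> 0.017."""
        f0, f1 = self._fits(-100.0, -100.0 + 15.89 / 2)
        _, p = lrt(f0, f1, df=1)
        assert p == pytest.approx(6.7e-5, rel=0.02)
        f0, f1 = self._fits(-100.0, -100.0 + 42.76 / 2)
        _, p = lrt(f0, f1, df=2)
        assert p == pytest.approx(5.2e-10, rel=0.02)
        f0, f1 = self._fits(-100.0, -100.0 + 5.72 / 2)
        _, p = lrt(f0, f1, df=1)
        assert p == pytest.approx(0.017, rel=0.02)

    def test_worse_extended_model_warns_and_floors(self):
        f0, f1 = self._fits(-100.0, -100.001)
        with pytest.warns(UserWarning, match="optimization"):
            stat, p = lrt(f0, f1, df=1)
        assert stat == 0.0 and p == 1.0

    def test_bic_comparison_arithmetic(self):
        f0, f1 = self._fits(-100.0, -90.0)
        delta = bic_compare(f0, f1, extra_params=1, n=100)
        assert delta == pytest.approx(-20.0 + np.log(100))
        assert delta < 0  # extended model preferred
        assert bic_compare(f0, f0, extra_params=0, n=100) == 0.0
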