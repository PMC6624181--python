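import numpy as np
import pytest

from _oracles import dense_update_B, dense_update_W, init_params, toy_design

from pharaoh_gee.gee_core import (
    ClusteredPhenotypes,
    CoefficientMatrix,
    PenaltyConfig,
    WeightMatrix,
    WorkingCorrelation,
    component_scores,
    estimate_alpha,
    estimate_dispersion,
    fit,
    pearson_residuals,
    update_B,
    update_W,
    working_covariance,
)


def _free_cols(W):
    M = np.zeros((W.T, W.K))
    M[np.arange(W.T), W.pathway_of_col] = W.w_star
    return M


class TestComponentScores:
    def test_single_gene_unit_weight_is_identity(self, rng):
        d = toy_design(rng, genes_per_pathway=(1,))
        W = WeightMatrix(w_star=np.array([1.0]), pathway_of_col=np.array([0]), K=1)
        F = component_scores(d, W)
        np.testing.assert_allclose(F[:, 1], d.X[:, 1], atol=1e-12)
        np.testing.assert_array_equal(F[:, 0], 1.0)

    def test_matches_double_sum_oracle(self, rng):
        d = toy_design(rng, genes_per_pathway=(3, 2))
        W, _ = init_params(d, 2, rng)
        F = component_scores(d, W)
        kcol = d.pathway_of_column()
        for k in range(d.K):
            expected = np.zeros(d.N)
            for t in np.nonzero(kcol == k)[0]:
                expected += d.X[:, 1 + t] * W.w_star[t]
            np.testing.assert_allclose(F[:, 1 + k], expected, atol=1e-10)


class TestWorkingCovariance:
    def test_gaussian_identity(self):
        R = WorkingCorrelation.identity(2)
        np.testing.assert_allclose(
            working_covariance(np.zeros(2), R, "gaussian", 1.0), np.eye(2)
        )

    def test_binomial_variance_function(self):
        R = WorkingCorrelation.identity(2)
        np.testing.assert_allclose(
            working_covariance(np.array([0.5, 0.5]), R, "binomial", 1.0),
            np.diag([0.25, 0.25]),
        )

    def test_binomial_exchangeable_off_diagonal(self):
        R = WorkingCorrelation(structure="exchangeable", Q=2, alpha=np.array([0.5]))
        sigma = working_covariance(np.array([0.5, 0.5]), R, "binomial", 1.0)
        np.testing.assert_allclose(sigma[0, 1], 0.125, atol=1e-12)

    def test_boundary_mean_clamped(self):
        R = WorkingCorrelation.identity(1)
        with pytest.warns(UserWarning, match="boundary"):
            sigma = working_covariance(np.array([0.0]), R, "binomial", 1.0)
        assert sigma[0, 0] > 0


class TestPearsonResiduals:
    @pytest.mark.parametrize(
        "family, y, mu, expected",
        [
            ("gaussian", 3.0, 1.0, 2.0),
            ("binomial", 1.0, 0.5, 1.0),
            ("binomial", 0.0, 0.8, -2.0),  # -0.8 / sqrt(0.16)
        ],
    )
    def test_hand_values(self, family, y, mu, expected):
        r = pearson_residuals(np.array([[y]]), np.array([[mu]]), family)
        np.testing.assert_allclose(r, [[expected]], rtol=1e-10)


class TestEstimateDispersion:
    def test_constant_residuals(self):
        r = np.full((10, 2), 3.0)
        # NQ - (K + sum T_k) = 20 - 6 = 14
        assert estimate_dispersion(r, K=1, T_ks=[5]) == pytest.approx(20 * 9.0 / 14)

    def test_zero_residuals(self):
        assert estimate_dispersion(np.zeros((10, 2)), K=1, T_ks=[5]) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        r = rng.normal(size=(9, 3))
        total = sum(r[i, j] ** 2 for i in range(9) for j in range(3))
        df = 9 * 3 - (2 + 4 + 3)
        assert estimate_dispersion(r, K=2, T_ks=[4, 3]) == pytest.approx(total / df)

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            estimate_dispersion(np.zeros((2, 2)), K=2, T_ks=[3, 3])


class TestEstimateAlpha:
    def test_independence_ignores_residuals(self, rng):
        R = estimate_alpha(rng.normal(size=(20, 3)), 1.0, "independence")
        np.testing.assert_array_equal(R.R, np.eye(3))

    def test_perfectly_correlated_columns(self, rng):
        col = rng.normal(size=50)
        r = np.column_stack([col, col])
        R = estimate_alpha(r, phi=float(np.mean(col**2)), structure="unstructured")
        assert R.R[0, 1] > 0.95

    def test_exchangeable_recovery_monte_carlo(self):
        r_ = np.random.default_rng(11)
        alpha_true, q, n = 0.4, 4, 2000
        cov = (1 - alpha_true) * np.eye(q) + alpha_true
        resid = r_.multivariate_normal(np.zeros(q), cov, size=n)
        R = estimate_alpha(resid, 1.0, "exchangeable")
        assert abs(R.alpha[0] - alpha_true) < 0.05

    def test_ar1_lag_structure(self):
        r_ = np.random.default_rng(12)
        q, a = 4, 0.6
        idx = np.arange(q)
        cov = a ** np.abs(idx[:, None] - idx[None, :])
        resid = r_.multivariate_normal(np.zeros(q), cov, size=3000)
        R = estimate_alpha(resid, 1.0, "ar1")
        assert abs(R.alpha[0] - a) < 0.05
        np.testing.assert_allclose(R.R[0, 2], R.alpha[0] ** 2, rtol=1e-10)


class TestUpdateOracleEquivalence:
    """The vectorized blockwise solvers must match dense stacked solves."""

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    @pytest.mark.parametrize("structure_alpha", [("independence", None), ("exchangeable", 0.3)])
    def test_update_B_matches_dense_oracle(self, family, structure_alpha, rng):
        structure, alpha = structure_alpha
        d = toy_design(rng, n=10, genes_per_pathway=(2, 2))
        Q = 3
        W, B = init_params(d, Q, rng)
        if family == "binomial":
            Y = ClusteredPhenotypes(Y=rng.integers(0, 2, size=(d.N, Q)).astype(float), family=family)
        else:
            Y = ClusteredPhenotypes(Y=rng.normal(size=(d.N, Q)), family=family)
        R = (
            WorkingCorrelation.identity(Q)
            if alpha is None
            else WorkingCorrelation(structure=structure, Q=Q, alpha=np.array([alpha]))
        )
        got = update_B(d, W, B, Y, R, phi=1.3, lambda_P=0.7)
        expected = dense_update_B(d, W, B, Y, R, 1.3, 0.7)
        np.testing.assert_allclose(got.B, expected, atol=1e-8)

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    @pytest.mark.parametrize("structure_alpha", [("independence", None), ("exchangeable", 0.3)])
    def test_update_W_matches_dense_oracle(self, family, structure_alpha, rng):
        structure, alpha = structure_alpha
        d = toy_design(rng, n=10, genes_per_pathway=(2, 2))
        Q = 2
        W, B = init_params(d, Q, rng)
        B.B[0, :] = 0.2  # nonzero intercepts exercise the offset path
        if family == "binomial":
            Y = ClusteredPhenotypes(Y=rng.integers(0, 2, size=(d.N, Q)).astype(float), family=family)
        else:
            Y = ClusteredPhenotypes(Y=rng.normal(size=(d.N, Q)), family=family)
        R = (
            WorkingCorrelation.identity(Q)
            if alpha is None
            else WorkingCorrelation(structure=structure, Q=Q, alpha=np.array([alpha]))
        )
        got = update_W(d, W, B, Y, R, phi=0.8, lambda_G=0.5)
        expected = dense_update_W(d, W, B, Y, R, 0.8, 0.5)
        np.testing.assert_allclose(got.w_star, expected, atol=1e-8)

    def test_update_B_ridge_limit_shrinks_to_zero(self, rng):
        d = toy_design(rng, n=10, genes_per_pathway=(2,))
        W, B = init_params(d, 2, rng)
        Y = ClusteredPhenotypes(Y=rng.normal(size=(d.N, 2)))
        got = update_B(d, W, B, Y, WorkingCorrelation.identity(2), 1.0, 1e12)
        assert np.abs(got.B[1:, :]).max() < 1e-6

    def test_update_W_ridge_limit_shrinks_to_zero(self, rng):
        d = toy_design(rng, n=10, genes_per_pathway=(2,))
        W, B = init_params(d, 2, rng)
        Y = ClusteredPhenotypes(Y=rng.normal(size=(d.N, 2)))
        got = update_W(d, W, B, Y, WorkingCorrelation.identity(2), 1.0, 1e12)
        assert np.abs(got.w_star).max() < 1e-6

    def test_single_pathway_single_gene_regression_slope(self, rng):
        # lambda_G = 0, beta fixed at 1: w solves simple regression of (y - b0) on x
        d = toy_design(rng, n=20, genes_per_pathway=(1,))
        W = WeightMatrix(w_star=np.array([0.3]), pathway_of_col=np.array([0]), K=1)
        B = CoefficientMatrix(B=np.array([[0.5], [1.0]]))
        y = 0.5 + 0.7 * d.X[:, 1] + rng.normal(scale=0.1, size=d.N)
        Y = ClusteredPhenotypes(Y=y[:, None])
        got = update_W(d, W, B, Y, WorkingCorrelation.identity(1), 1.0, 0.0)
        x = d.X[:, 1]
        slope = float(x @ (y - 0.5) / (x @ x))
        assert got.w_star[0] == pytest.approx(slope, rel=1e-10)


class TestFit:
    def test_gaussian_single_component_matches_ols_product(self, rng):
        d = toy_design(rng, n=30, genes_per_pathway=(1,))
        y = 1.0 + 0.8 * d.X[:, 1] + rng.normal(scale=0.3, size=d.N)
        Y = ClusteredPhenotypes(Y=y[:, None])
        res = fit(d, Y, PenaltyConfig(0.0, 0.0), structure="independence", tol=1e-9)
        coeffs, *_ = np.linalg.lstsq(d.X, y, rcond=None)
        product = res.W.w_star[0] * res.B.B[1, 0]
        assert product == pytest.approx(coeffs[1], abs=1e-6)
        # fitted values match unrestricted least squares
        np.testing.assert_allclose(res.F @ res.B.B, (d.X @ coeffs)[:, None], atol=1e-6)

    def test_structural_zeros_exact(self, study_replicate):
        _, design, Y = study_replicate
        res = fit(design, Y, PenaltyConfig(1.0, 1.0))
        Wfull = res.W.full
        kcol = design.pathway_of_column()
        for t in range(design.T):
            for c in range(design.K + 1):
                if c != kcol[t] + 1:
                    assert Wfull[t + 1, c] == 0.0
        assert Wfull[0, 0] == 1.0

    def test_sign_convention_largest_weight_positive(self, study_replicate):
        _, design, Y = study_replicate
        res = fit(design, Y, PenaltyConfig(1.0, 1.0))
        kcol = design.pathway_of_column()
        for k in range(design.K):
            blk = res.W.w_star[kcol == k]
            assert blk[np.argmax(np.abs(blk))] > 0

    def test_eta_invariant_under_block_rescaling(self, study_replicate):
        _, design, Y = study_replicate
        res = fit(design, Y, PenaltyConfig(1.0, 1.0))
        kcol = design.pathway_of_column()
        w2 = res.W.w_star.copy()
        B2 = res.B.B.copy()
        c = 3.7
        w2[kcol == 0] *= c
        B2[1, :] /= c
        W2 = WeightMatrix(w_star=w2, pathway_of_col=kcol, K=design.K)
        F2 = component_scores(design, W2)
        np.testing.assert_allclose(F2 @ B2, res.F @ res.B.B, atol=1e-10)

    def test_fixed_point_satisfies_both_block_updates(self, study_replicate):
        _, design, Y = study_replicate
        res = fit(design, Y, PenaltyConfig(1.0, 1.0), tol=1e-8)
        assert res.converged
        B_next = update_B(design, res.W, res.B, Y, res.correlation, res.phi, 1.0)
        W_next = update_W(design, res.W, B_next, Y, res.correlation, res.phi, 1.0)
        assert np.abs(B_next.B - res.B.B).max() < 1e-5
        assert np.abs(W_next.w_star - res.W.w_star).max() < 1e-5

    def test_ridge_monotonicity_in_both_penalties(self, rng):
        d = toy_design(rng, n=40, genes_per_pathway=(3, 3))
        y = d.X[:, 1] - 0.5 * d.X[:, 4] + rng.normal(scale=0.5, size=(d.N,))
        Y = ClusteredPhenotypes(Y=np.column_stack([y, y + rng.normal(scale=0.5, size=d.N)]))
        grid = [0.01, 0.1, 1.0, 10.0, 100.0]
        b_norms = [
            np.linalg.norm(fit(d, Y, PenaltyConfig(1.0, lam)).B.B[1:, :]) for lam in grid
        ]
        w_norms = [
            np.linalg.norm(fit(d, Y, PenaltyConfig(lam, 1.0)).W.w_star) for lam in grid
        ]
        assert all(b_norms[i + 1] <= b_norms[i] + 1e-9 for i in range(4))
        assert all(w_norms[i + 1] <= w_norms[i] + 1e-9 for i in range(4))

    def test_gee_consistency_under_misspecified_correlation(self):
        # exchangeable-correlated gaussian noise, fitted with independence:
        # the identified product w*beta still recovers the generating value
        r_ = np.random.default_rng(21)
        n = 4000
        x = r_.normal(size=n)
        x = (x - x.mean()) / np.sqrt(np.mean((x - x.mean()) ** 2))
        from pharaoh_gee.collapse import standardize_design

        d = standardize_design(
            np.column_stack([np.ones(n), x]), [("pw1", "g1")], ["pw1"]
        )
        true_effect = 0.6
        noise = r_.multivariate_normal(np.zeros(2), [[1, 0.5], [0.5, 1]], size=n)
        Y = ClusteredPhenotypes(Y=true_effect * d.X[:, 1:2] + noise)
        res = fit(d, Y, PenaltyConfig(1e-6, 1e-6), structure="independence")
        product = res.W.w_star[0] * res.B.B[1, :]
        np.testing.assert_allclose(product, true_effect, atol=0.05)

    def test_nonconvergence_warns_and_flags(self, study_replicate):
        _, design, Y = study_replicate
        with pytest.warns(UserWarning, match="did not converge"):
            res = fit(design, Y, PenaltyConfig(1.0, 1.0), max_iter=2)
        assert not res.converged

    @pytest.mark.parametrize("structure", ["independence", "exchangeable", "ar1", "unstructured"])
    def test_fit_converges_under_every_correlation_structure(self, structure, rng):
        d = toy_design(rng, n=60, genes_per_pathway=(2, 2))
        base = rng.normal(size=(d.N, 1))
        Y = ClusteredPhenotypes(Y=base + 0.5 * rng.normal(size=(d.N, 3)))
        res = fit(d, Y, PenaltyConfig(1.0, 1.0), structure=structure)
        assert res.converged
        assert np.linalg.eigvalsh(res.correlation.R).min() > 0
        if structure == "exchangeable":
            assert res.correlation.alpha[0] > 0.3  # shared factor induces correlation

    def test_component_standardization_flag(self, rng):
        d = toy_design(rng, n=50, genes_per_pathway=(3, 3))
        y = d.X[:, 1] + rng.normal(scale=0.5, size=d.N)
        Y = ClusteredPhenotypes(Y=np.column_stack([y, y]))
        res = fit(d, Y, PenaltyConfig(1.0, 1.0), standardize_components=True)
        comps = d.X[:, 1:] @ _free_cols(res.W)
        np.testing.assert_allclose(comps.std(axis=0), 1.0, rtol=1e-6)

    def test_binomial_dispersion_fixed_at_one_by_default(self, study_replicate):
        _, design, Y = study_replicate
        res = fit(design, Y, PenaltyConfig(1.0, 1.0))
        assert res.phi == 1.0
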