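"""Multinomial sparse-group-Lasso solver against independent convex
minimizers and closed-form endpoints."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from oracles import generic_convex_minimum, reference_objective

from ramrsgl.msgl_solver import (
    Coefficients,
    PenaltySpec,
    class_scores,
    compute_lambda_max,
    fit_path,
    group_is_zero,
    negative_log_likelihood,
    penalty_value,
    predict,
    soft_threshold,
    softmax_probabilities,
)


class TestElementaryOperations:
    def test_class_scores_zero_beta(self):
        coef = Coefficients(beta0=np.array([1.0, 0.0, -1.0]), beta=np.zeros((3, 4)))
        assert np.allclose(class_scores(coef, np.ones(4)), [1.0, 0.0, -1.0])

    def test_class_scores_identity_beta(self):
        coef = Coefficients(beta0=np.zeros(2), beta=np.eye(2))
        assert np.allclose(class_scores(coef, np.array([2.0, 3.0])), [2.0, 3.0])

    def test_class_scores_dimension_mismatch(self):
        coef = Coefficients(beta0=np.zeros(2), beta=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            class_scores(coef, np.zeros(4))

    def test_softmax_uniform_and_direct(self):
        assert np.allclose(softmax_probabilities(np.zeros(4)), 0.25)
        assert np.allclose(softmax_probabilities(np.array([0.0, np.log(3.0)])), [0.25, 0.75])

    def test_softmax_shift_invariance(self):
        s = np.array([0.3, -1.2, 2.0])
        assert np.allclose(softmax_probabilities(s), softmax_probabilities(s + 17.0))

    def test_nll_uniform_model_is_log_k(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        Y = np.eye(3)[rng.integers(0, 3, 10)]
        coef = Coefficients(beta0=np.zeros(3), beta=np.zeros((3, 4)))
        assert negative_log_likelihood(X, Y, coef) == pytest.approx(np.log(3))

    def test_nll_direct_arithmetic(self):
        # one sample, scores (0, ln 3), true class 2 -> -log(0.75)
        X = np.ones((1, 1))
        Y = np.array([[0.0, 1.0]])
        coef = Coefficients(beta0=np.array([0.0, np.log(3.0)]), beta=np.zeros((2, 1)))
        assert negative_log_likelihood(X, Y, coef) == pytest.approx(np.log(4.0 / 3.0))

    def test_nll_rejects_non_one_hot(self):
        coef = Coefficients(beta0=np.zeros(2), beta=np.zeros((2, 1)))
        with pytest.raises(ValueError):
            negative_log_likelihood(np.ones((1, 1)), np.array([[0.5, 0.5]]), coef)

    def test_penalty_direct_arithmetic(self):
        # K=1, one group of size 2, beta=(3,4), w=(1,2), alpha=0.5, lam=1
        spec = PenaltySpec(alpha=0.5, lam=1.0, groups=np.array([1, 1]),
                           group_sizes=np.array([2]), w=np.array([1.0, 2.0]))
        coef = Coefficients(beta0=np.zeros(1), beta=np.array([[3.0, 4.0]]))
        assert penalty_value(coef, spec) == pytest.approx(0.5 * np.sqrt(2) * 5 + 0.5 * 11)

    def test_penalty_endpoints(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(size=(2, 4))
        groups, sizes, w = np.array([1, 1, 2, 2]), np.array([2, 2]), rng.uniform(0.5, 2, 4)
        coef = Coefficients(beta0=np.zeros(2), beta=beta)
        l1_only = penalty_value(coef, PenaltySpec(1.0, 2.0, groups, sizes, w))
        assert l1_only == pytest.approx(2.0 * np.sum(np.abs(beta) * w))
        gl_only = penalty_value(coef, PenaltySpec(0.0, 2.0, groups, sizes, w))
        expected = 2.0 * sum(
            np.sqrt(2) * np.linalg.norm(beta[:, groups == l], axis=1).sum() for l in (1, 2)
        )
        assert gl_only == pytest.approx(expected)

    @pytest.mark.parametrize("z,tau,expected", [(3, 2, 1), (-3, 2, -1), (1, 2, 0)])
    def test_soft_threshold(self, z, tau, expected):
        assert soft_threshold(z, tau) == expected


class TestGroupIsZero:
    def test_zero_gradient(self):
        assert group_is_zero(np.zeros(3), alpha=0.5, lam=1.0, m_l=3, w_block=np.ones(3))

    def test_alpha_one_endpoint(self):
        g = np.array([0.5, -1.5])
        w = np.array([1.0, 2.0])
        assert group_is_zero(g, 1.0, 0.76, 2, w)  # |g|/w = (0.5, 0.75) <= 0.76
        assert not group_is_zero(g, 1.0, 0.74, 2, w)

    def test_agrees_with_numeric_one_block_minimizer(self):
        rng = np.random.default_rng(2)
        m, alpha = 3, 0.4
        w = rng.uniform(0.5, 1.5, m)
        g = rng.normal(size=m) * 0.3

        def solve_block(lam):
            # min_b g.b + 0.5||b||^2 + (1-a)lam sqrt(m)||b|| + a lam sum w|b|
            def f(z):
                b = z[:m] - z[m:]
                return (
                    g @ b + 0.5 * b @ b
                    + (1 - alpha) * lam * np.sqrt(m) * np.sqrt(b @ b + 1e-14)
                    + alpha * lam * np.sum(w * (z[:m] + z[m:]))
                )
            res = minimize(f, np.zeros(2 * m), method="L-BFGS-B",
                           bounds=[(0, None)] * (2 * m), options={"ftol": 1e-16})
            return np.linalg.norm(res.x[:m] - res.x[m:])

        for lam in (0.05, 0.15, 0.5):
            numeric_zero = solve_block(lam) <= 1e-6
            assert group_is_zero(g, alpha, lam, m, w) == numeric_zero


class TestLambdaMax:
    def test_fit_at_lambda_max_all_zero(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        lam_max = compute_lambda_max(X, Y, 0.5, groups, sizes, w, standardize=False)
        path = fit_path(X, Y, groups, sizes, w, alpha=0.5,
                        lambdas=np.array([lam_max]), standardize=False)
        assert np.all(path[0].coef.beta == 0.0)
        prop = Y.mean(axis=0)
        b0 = path[0].coef.beta0
        assert np.allclose(b0 - b0.mean(), np.log(prop) - np.log(prop).mean(), atol=1e-6)

    def test_half_lambda_max_activates_a_block(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        lam_max = compute_lambda_max(X, Y, 0.5, groups, sizes, w, standardize=False)
        path = fit_path(X, Y, groups, sizes, w, alpha=0.5,
                        lambdas=np.array([0.5 * lam_max]), standardize=False)
        assert path[0].n_nonzero_groups >= 1

    def test_weight_scaling_homogeneity_at_alpha_one(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        lm = compute_lambda_max(X, Y, 1.0, groups, sizes, w, standardize=False)
        lm_scaled = compute_lambda_max(X, Y, 1.0, groups, sizes, 2.5 * w, standardize=False)
        assert lm_scaled == pytest.approx(lm / 2.5)

    def test_single_class_rejected(self):
        X = np.random.default_rng(3).normal(size=(5, 2))
        with pytest.raises(ValueError):
            compute_lambda_max(X, np.ones((5, 1)), 0.5, np.array([1, 1]),
                               np.array([2]), np.ones(2))


class TestFitPath:
    def test_matches_generic_convex_minimizer(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        lam_max = compute_lambda_max(X, Y, 0.5, groups, sizes, w, standardize=False)
        lam = 0.3 * lam_max
        path = fit_path(X, Y, groups, sizes, w, alpha=0.5,
                        lambdas=np.array([lam]), standardize=False)
        ours = reference_objective(X, Y, 0.5, lam, groups, sizes, w,
                                   path[0].coef.beta0, path[0].coef.beta)
        oracle = generic_convex_minimum(X, Y, 0.5, lam, groups, sizes, w)
        assert abs(ours - oracle) <= 1e-6
        assert path[0].kkt_residual <= 1e-4

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_endpoint_penalties_match_oracle(self, alpha, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        w_use = np.ones_like(w) if alpha == 1.0 else w
        lam_max = compute_lambda_max(X, Y, alpha, groups, sizes, w_use, standardize=False)
        lam = 0.3 * lam_max
        path = fit_path(X, Y, groups, sizes, w_use, alpha=alpha,
                        lambdas=np.array([lam]), standardize=False)
        ours = reference_objective(X, Y, alpha, lam, groups, sizes, w_use,
                                   path[0].coef.beta0, path[0].coef.beta)
        oracle = generic_convex_minimum(X, Y, alpha, lam, groups, sizes, w_use)
        assert ours <= oracle + 1e-5

    def test_objective_decreases_along_path_and_kkt_bounded(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        path = fit_path(X, Y, groups, sizes, w, alpha=0.5, n_lambda=12,
                        lambda_min_ratio=1e-2, standardize=False, tol=1e-5)
        objs = [pt.objective for pt in path]
        assert all(np.isfinite(objs))
        for pt in path:
            assert pt.kkt_residual <= 10 * 1e-5
        assert path[0].n_nonzero_genes == 0
        assert path[-1].n_nonzero_genes >= path[0].n_nonzero_genes

    def test_training_accuracy_on_separable_fixture(self):
        rng = np.random.default_rng(10)
        n, K = 30, 3
        groups = np.repeat([1, 2], 3)
        sizes = np.array([3, 3])
        X = rng.normal(size=(n, 6))
        y = rng.integers(0, K, n)
        X[:, 0] += 6.0 * (y == 0)
        X[:, 1] += 6.0 * (y == 1)
        X[:, 2] += 6.0 * (y == 2)  # group 1 is the planted discriminative group
        Y = np.eye(K)[y]
        path = fit_path(X, Y, groups, sizes, np.ones(6), alpha=0.5, n_lambda=20,
                        lambda_min_ratio=1e-3)
        pt = path[-1]
        labels, _ = predict(pt.coef, X)
        assert np.mean(labels - 1 == y) == 1.0
        assert np.any(pt.coef.beta[:, :3] != 0.0)

    def test_doubling_weight_never_increases_coefficient(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        lam = 0.3 * compute_lambda_max(X, Y, 1.0, groups, sizes, w, standardize=False)
        base = fit_path(X, Y, groups, sizes, w, alpha=1.0,
                        lambdas=np.array([lam]), standardize=False)[0].coef.beta
        for j in range(3):
            w2 = w.copy()
            w2[j] *= 2.0
            bumped = fit_path(X, Y, groups, sizes, w2, alpha=1.0,
                              lambdas=np.array([lam]), standardize=False)[0].coef.beta
            assert np.all(np.abs(bumped[:, j]) <= np.abs(base[:, j]) + 1e-6)

    def test_increasing_lambdas_rejected(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        with pytest.raises(ValueError):
            fit_path(X, Y, groups, sizes, w, lambdas=np.array([0.1, 0.2]))

    def test_cross_class_grouping_variant_runs(self, tiny_multinomial_instance):
        X, Y, y, groups, sizes, w = tiny_multinomial_instance
        path = fit_path(X, Y, groups, sizes, w, alpha=0.5, n_lambda=5,
                        lambda_min_ratio=0.1, cross_class=True)
        assert path[0].n_nonzero_genes == 0
        assert all(pt.kkt_residual <= 1e-4 for pt in path)


class TestPredict:
    def test_null_model_predicts_prior(self):
        coef = Coefficients(beta0=np.log(np.array([0.5, 0.3, 0.2])), beta=np.zeros((3, 2)))
        labels, probs = predict(coef, np.zeros((4, 2)))
        assert np.all(labels == 1)
        assert np.allclose(probs, [0.5, 0.3, 0.2])

    def test_exact_tie_goes_to_lowest_class(self):
        coef = Coefficients(beta0=np.zeros(3), beta=np.zeros((3, 2)))
        labels, _ = predict(coef, np.ones((2, 2)))
        assert np.all(labels == 1)

    def test_two_class_linear_rule(self):
        d = np.array([1.0, -2.0])
        coef = Coefficients(beta0=np.zeros(2), beta=np.vstack([d, np.zeros(2)]))
        rng = np.random.default_rng(11)
        Xn = rng.normal(size=(20, 2))
        labels, _ = predict(coef, Xn)
        expected = np.where(Xn @ d >= 0.0, 1, 2)
        assert np.array_equal(labels, expected)
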