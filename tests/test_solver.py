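"""Group-elastic-net solver: limits, oracles, KKT, minimum norm."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet, Lasso

from oracles import (group_objective_value, irls_group_elastic_net,
                     random_grouped_problem)
from roiglasso.glasso_solver import (PenaltyConfig, fit_group_elastic_net,
                                     fit_minimum_norm, fit_path,
                                     kkt_residual, lambda_grid, lambda_max)


class TestLambdaMax:
    def test_orthogonal_observations_give_zero(self):
        X = np.vstack([np.eye(3), -np.eye(3)])        # centred columns
        Y = np.ones((6, 2))                            # pure intercept
        assert lambda_max((X, Y, [np.arange(3)], [1.0])) == 0.0

    def test_all_zero_just_above_threshold(self):
        rng = np.random.default_rng(0)
        X, Y, groups, gammas = random_grouped_problem(rng)
        lmax = lambda_max((X, Y, groups, gammas))
        fit = fit_group_elastic_net((X, Y, groups, gammas),
                                    lmax * (1 + 1e-6), alpha=0.0)
        assert np.all(fit.beta == 0)
        np.testing.assert_allclose(fit.intercept, Y.mean(axis=0))

    def test_matches_direct_maximisation(self):
        rng = np.random.default_rng(1)
        X, Y, groups, gammas = random_grouped_problem(rng, n_groups=3)
        Yc = Y - Y.mean(axis=0)
        direct = max(np.linalg.norm(X[:, g].T @ Yc) / gammas[i]
                     for i, g in enumerate(groups))
        assert lambda_max((X, Y, groups, gammas)) == pytest.approx(direct)

    def test_zero_gamma_with_correlation_rejected(self):
        rng = np.random.default_rng(2)
        X, Y, groups, gammas = random_grouped_problem(rng, n_groups=2)
        gammas = np.array(gammas, dtype=float)
        gammas[0] = 0.0
        with pytest.raises(ValueError):
            lambda_max((X, Y, groups, gammas))


class TestLambdaGrid:
    def test_log_spacing_example(self):
        np.testing.assert_allclose(lambda_grid(1.0, 3, 0.01),
                                   [1.0, 0.1, 0.01])

    def test_first_element_is_lmax(self):
        assert lambda_grid(7.3, 11, 1e-2)[0] == pytest.approx(7.3)

    def test_constant_adjacent_ratio(self):
        g = lambda_grid(2.0, 100, 1e-3)
        ratios = g[1:] / g[:-1]
        assert np.ptp(ratios) < 1e-12


class TestGroupElasticNet:
    def test_ridge_closed_form_at_lambda_zero(self):
        rng = np.random.default_rng(3)
        X, Y, groups, gammas = random_grouped_problem(rng,
                                                      sparse_truth=False)
        alpha = 0.7
        fit = fit_group_elastic_net((X, Y, groups, gammas), 0.0, alpha,
                                    tol=1e-12)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        closed = np.linalg.solve(Xc.T @ Xc + 2 * alpha * np.eye(X.shape[1]),
                                 Xc.T @ Yc)
        np.testing.assert_allclose(fit.beta, closed, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.0, 0.3])
    def test_singleton_groups_match_sklearn(self, alpha):
        # singleton groups with unit weights and one response column:
        # the objective is the plain lasso / elastic net
        rng = np.random.default_rng(4)
        n, p = 40, 7
        X = rng.standard_normal((n, p))
        y = X[:, :3] @ np.array([1.5, -2.0, 1.0]) + \
            0.3 * rng.standard_normal(n)
        groups = [np.array([j]) for j in range(p)]
        gammas = np.ones(p)
        lam = 4.0
        fit = fit_group_elastic_net((X, y, groups, gammas), lam, alpha,
                                    tol=1e-12)
        if alpha == 0.0:
            sk = Lasso(alpha=lam / n, fit_intercept=True, tol=1e-14,
                       max_iter=100000)
        else:
            a = (lam + 2 * alpha) / n
            l1r = lam / (lam + 2 * alpha)
            sk = ElasticNet(alpha=a, l1_ratio=l1r, fit_intercept=True,
                            tol=1e-14, max_iter=100000)
        sk.fit(X, y)
        np.testing.assert_allclose(fit.beta[:, 0], sk.coef_, atol=2e-6)

    def test_matches_irls_oracle_and_kkt(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X, Y, groups, gammas = random_grouped_problem(rng)
            lmax = lambda_max((X, Y, groups, gammas))
            lam = 0.3 * lmax
            alpha = 0.1
            fit = fit_group_elastic_net((X, Y, groups, gammas), lam,
                                        alpha, tol=1e-10)
            assert fit.converged
            assert kkt_residual(X, Y, fit.beta, lam, alpha, gammas,
                                groups) < 1e-6
            b_o = irls_group_elastic_net(X, Y, groups, gammas, lam, alpha)
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            obj_o = group_objective_value(Xc, Yc, b_o, lam, alpha,
                                          gammas, groups)
            assert fit.objective <= obj_o + 1e-6

    def test_group_zero_or_dense(self):
        rng = np.random.default_rng(6)
        X, Y, groups, gammas = random_grouped_problem(rng)
        lam = 0.4 * lambda_max((X, Y, groups, gammas))
        fit = fit_group_elastic_net((X, Y, groups, gammas), lam, 0.05)
        for g in groups:
            block = fit.beta[g]
            assert np.all(block == 0) or np.linalg.norm(block) > 0

    def test_objective_monotone_over_sweeps(self):
        rng = np.random.default_rng(7)
        X, Y, groups, gammas = random_grouped_problem(rng)
        lam = 0.2 * lambda_max((X, Y, groups, gammas))
        hist = []
        fit_group_elastic_net((X, Y, groups, gammas), lam, 0.1,
                              history=hist)
        diffs = np.diff(hist)
        assert np.all(diffs <= 1e-9 * max(1.0, abs(hist[0])))


class TestPath:
    def test_single_point_grid_all_zero(self):
        rng = np.random.default_rng(8)
        X, Y, groups, gammas = random_grouped_problem(rng)
        lmax = lambda_max((X, Y, groups, gammas))
        path = fit_path((X, Y, groups, gammas),
                        PenaltyConfig(lambda_grid=np.array([lmax]),
                                      alpha=0.1))
        assert np.all(path.betas[0] == 0)
        assert path.r2[0] == pytest.approx(0.0, abs=1e-12)

    def test_r2_monotone_as_lambda_decreases(self):
        rng = np.random.default_rng(9)
        X, Y, groups, gammas = random_grouped_problem(rng,
                                                      sparse_truth=False)
        path = fit_path((X, Y, groups, gammas),
                        PenaltyConfig(n_lambda=25, alpha=0.05, tol=1e-10))
        assert np.all(np.diff(path.r2) >= -1e-8)
        assert path.r2[0] == pytest.approx(0.0, abs=1e-10)

    def test_convergence_flags_propagate(self):
        rng = np.random.default_rng(10)
        X, Y, groups, gammas = random_grouped_problem(rng)
        path = fit_path((X, Y, groups, gammas),
                        PenaltyConfig(n_lambda=5, alpha=0.1, max_iter=1))
        assert path.converged.dtype == bool


class TestMinimumNorm:
    def test_huge_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(11)
        F = rng.standard_normal((6, 15))
        Y = rng.standard_normal((6, 4))
        path = fit_minimum_norm([(F, Y)], lambdas=np.array([1e12, 1.0]))
        assert np.linalg.norm(path[0].beta_at(0)) < 1e-8

    def test_orthogonal_rows_interpolate_at_zero(self):
        rng = np.random.default_rng(12)
        A = np.linalg.qr(rng.standard_normal((10, 6)))[0].T   # 6x10 rows
        Y = rng.standard_normal((6, 3))
        path = fit_minimum_norm([(A, Y)], lambdas=np.array([1.0, 0.0]))
        beta = path[0].beta_at(1)
        Yc = Y - Y.mean(axis=0)
        np.testing.assert_allclose(A @ beta, Yc, atol=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(13)
        F = rng.standard_normal((8, 20))
        Y = rng.standard_normal((8, 3))
        lam = 2.5
        path = fit_minimum_norm([(F, Y)], lambdas=np.array([lam]))
        Yc = Y - Y.mean(axis=0)
        direct = F.T @ np.linalg.solve(F @ F.T + lam * np.eye(8), Yc)
        np.testing.assert_allclose(path[0].beta_at(0), direct, atol=1e-8)

    def test_stacked_problem_decouples(self):
        rng = np.random.default_rng(14)
        F1 = rng.standard_normal((6, 11))
        F2 = rng.standard_normal((6, 9))
        Y1 = rng.standard_normal((6, 2))
        Y2 = rng.standard_normal((6, 2))
        lam = 3.0
        sep = fit_minimum_norm([(F1, Y1), (F2, Y2)],
                               lambdas=np.array([lam]))
        # block-diagonal stacked system solved directly
        Fs = np.block([[F1, np.zeros((6, 9))], [np.zeros((6, 11)), F2]])
        Ys = np.vstack([Y1 - Y1.mean(0), Y2 - Y2.mean(0)])
        stacked = Fs.T @ np.linalg.solve(Fs @ Fs.T + lam * np.eye(12), Ys)
        np.testing.assert_allclose(
            np.vstack([sep[0].beta_at(0), sep[1].beta_at(0)]), stacked,
            atol=1e-10)

    def test_exact_df_matches_hat_trace(self):
        rng = np.random.default_rng(15)
        F = rng.standard_normal((7, 12))
        Y = rng.standard_normal((7, 3))
        lam = 1.7
        path = fit_minimum_norm([(F, Y)], lambdas=np.array([lam]))
        N, T = Y.shape
        J = np.full((N, N), 1.0 / N)
        Hc = F @ F.T @ np.linalg.inv(F @ F.T + lam * np.eye(N))
        H = J + Hc @ (np.eye(N) - J)
        assert path[0].df[0] == pytest.approx(T * np.trace(H), rel=1e-10)
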