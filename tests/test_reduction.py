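"""Spatial/temporal filtering, stacking and back-projection."""

import numpy as np
import pytest

from roiglasso.forward_sim import simulate_dataset
from roiglasso.reduction import (backproject, filter_forward, spatial_basis,
                                 stack_problem, temporal_basis)


class TestSpatialBasis:
    def test_orthonormal_columns(self):
        rng = np.random.default_rng(0)
        b = spatial_basis(rng.standard_normal((12, 9)), K=5)
        np.testing.assert_allclose(b.P.T @ b.P, np.eye(5), atol=1e-12)

    def test_matches_full_svd_up_to_sign(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((8, 6))
        b = spatial_basis(F, K=5)
        Fc = F - F.mean(axis=0)
        _, _, Vt = np.linalg.svd(Fc)
        for j in range(5):
            v = Vt[j]
            dot = abs(float(v @ b.P[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_principal_axes_recovered(self):
        # orthogonal columns of distinct norms: right singular vectors are
        # the coordinate axes (after centering is made exact by zero-mean
        # columns)
        Q, _ = np.linalg.qr(np.random.default_rng(3).standard_normal((9, 4)))
        Q = Q - Q.mean(axis=0)
        # re-orthogonalise the centred frame, then scale
        Q, _ = np.linalg.qr(Q)
        F = Q * np.array([5.0, 3.0, 2.0, 1.0])
        b = spatial_basis(F, K=4)
        M = np.abs(b.P)
        np.testing.assert_allclose(M, np.eye(4), atol=1e-8)

    def test_rank_deficient_block_padded_and_flagged(self):
        F = np.outer(np.arange(6.0), np.ones(4))    # centred rank 1... 0
        F[:, 1] *= 2
        b = spatial_basis(F, K=3)
        assert b.rank_deficient
        assert b.n_informative < 3
        np.testing.assert_allclose(b.P.T @ b.P, np.eye(3), atol=1e-12)


class TestFilterForward:
    def test_identity_basis_returns_centered_block(self):
        rng = np.random.default_rng(5)
        F = rng.standard_normal((10, 3))
        b = spatial_basis(F, K=3)
        X = filter_forward(F, b)
        # X = Fc P with orthonormal square P: reconstruct exactly
        Fc = F - F.mean(axis=0)
        np.testing.assert_allclose(X @ b.P.T, Fc, atol=1e-10)

    def test_rank_k_reconstruction(self):
        rng = np.random.default_rng(6)
        F = rng.standard_normal((12, 5)) @ rng.standard_normal((5, 8))
        F = F - F.mean(axis=0)
        b = spatial_basis(F, K=5)
        X = filter_forward(F, b)
        np.testing.assert_allclose(X @ b.P.T, F - F.mean(axis=0),
                                   atol=1e-9 * np.abs(F).max())

    def test_zero_block_and_shape_mismatch(self):
        b = spatial_basis(np.zeros((6, 4)), K=2)
        assert b.rank_deficient
        np.testing.assert_array_equal(
            filter_forward(np.zeros((6, 4)), b), np.zeros((6, 2)))
        with pytest.raises(ValueError):
            filter_forward(np.zeros((6, 5)), b)


class TestTemporalBasis:
    def test_threshold_arithmetic(self):
        # singular values {10, 1, 0.1}: the first component explains
        # 100/101.01 = 0.99001 of the variance, so d = 1
        rng = np.random.default_rng(7)
        U, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        V, _ = np.linalg.qr(rng.standard_normal((5, 3)))
        Y = U @ np.diag([10.0, 1.0, 0.1]) @ V.T
        assert temporal_basis(Y, 0.99).d == 1

    def test_exact_rank_two(self):
        rng = np.random.default_rng(8)
        Y = np.outer(rng.standard_normal(10), rng.standard_normal(7))
        Y += np.outer(rng.standard_normal(10), rng.standard_normal(7))
        assert temporal_basis(Y, 0.99).d == 2

    def test_matches_cumulative_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            Y = rng.standard_normal((12, 9))
            tb = temporal_basis(Y, 0.9)
            s2 = np.linalg.svd(Y, compute_uv=False) ** 2
            d_oracle = next(k + 1 for k in range(s2.size)
                            if s2[:k + 1].sum() / s2.sum() >= 0.9 - 1e-12)
            assert tb.d == d_oracle
            np.testing.assert_allclose(tb.V_d.T @ tb.V_d, np.eye(tb.d),
                                       atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            temporal_basis(np.empty((0, 0)))


class TestStacking:
    def test_single_subject_shapes(self, small_dataset):
        forwards, truths, recordings = small_dataset
        prob = stack_problem([(forwards[0], recordings[0])], K=3)
        R = forwards[0].n_rois
        assert prob.X.shape == (forwards[0].n_sensors, 3 * R)
        assert not np.any(np.all(prob.X == 0, axis=0))

    def test_multi_subject_block_structure(self):
        forwards, truths, recordings = simulate_dataset(
            5, n_rois=18, size_profile=(8,) * 18, n_sensors=16, T=21,
            active_rois=(1, 3), seed=42)
        prob = stack_problem(list(zip(forwards, recordings)), K=5)
        N = 16
        assert prob.X.shape == (5 * N, 5 * 5 * 18)
        for i in range(18):
            for k in range(5):
                cols = prob.subject_cols[i][k]
                block = np.ones(5 * N, dtype=bool)
                block[k * N:(k + 1) * N] = False
                assert np.all(prob.X[np.ix_(block, cols)] == 0)

    def test_group_weights_are_frobenius_norms(self, small_dataset):
        forwards, truths, recordings = small_dataset
        prob = stack_problem(list(zip(forwards, recordings)), K=3)
        for i, cols in enumerate(prob.group_cols):
            assert prob.gammas[i] == pytest.approx(
                np.linalg.norm(prob.X[:, cols]))
        # Frobenius norm of an identity-like block: sqrt of column count
        assert np.linalg.norm(np.eye(5)) == pytest.approx(np.sqrt(5))

    def test_inconsistent_roi_order_rejected(self, small_dataset):
        forwards, truths, recordings = small_dataset
        bad = forwards[1]
        bad_rois = list(bad.rois)[::-1]
        from roiglasso.forward_sim import SubjectForward
        bad = SubjectForward(subject_id=1, rois=bad_rois,
                             F_blocks=bad.F_blocks[::-1],
                             n_sensors=bad.n_sensors)
        with pytest.raises(ValueError):
            stack_problem([(forwards[0], recordings[0]),
                           (bad, recordings[1])])


@pytest.fixture(scope="module")
def problem(small_dataset):
    forwards, truths, recordings = small_dataset
    return stack_problem(list(zip(forwards, recordings)), K=3)


class TestBackprojection:
    def test_zero_maps_to_zero(self, problem):
        beta = np.zeros((problem.X.shape[1], problem.d))
        for est in backproject(beta, problem):
            assert np.all(est == 0)

    def test_norm_preserved(self, problem):
        rng = np.random.default_rng(11)
        beta = rng.standard_normal((problem.X.shape[1], problem.d))
        ests = backproject(beta, problem)
        total = np.sqrt(sum(np.sum(e ** 2) for e in ests))
        assert total == pytest.approx(np.linalg.norm(beta), rel=1e-10)

    def test_projection_idempotence(self, problem, small_dataset):
        # anything already in span(P) x span(V_d) survives the round trip
        forwards, _, _ = small_dataset
        rng = np.random.default_rng(12)
        beta = rng.standard_normal((problem.X.shape[1], problem.d))
        ests = backproject(beta, problem)
        # re-filter: beta_tilde = P^t beta_hat V_d
        back = np.empty_like(beta)
        for k, est in enumerate(ests):
            for i, sl in enumerate(forwards[k].roi_slices):
                P = problem.spatial[k][i].P
                cols = problem.subject_cols[i][k]
                back[cols] = P.T @ est[sl] @ problem.temporal.V_d
        np.testing.assert_allclose(back, beta, atol=1e-10)

    def test_shape_mismatch_rejected(self, problem):
        with pytest.raises(ValueError):
            backproject(np.zeros((3, problem.d)), problem)


def test_objective_equivalence_under_temporal_filtering(small_dataset):
    """The full and temporally filtered objectives agree up to the
    constant energy outside span(V_d), for any coefficients."""
    forwards, truths, recordings = small_dataset
    prob = stack_problem(list(zip(forwards, recordings)), K=3)
    rng = np.random.default_rng(13)
    X = prob.X
    Xc = X - X.mean(axis=0)
    Y = prob.Y_stack
    Yc = Y - Y.mean(axis=0)
    Vd = prob.temporal.V_d
    Ytc = Yc @ Vd
    lam, alpha = 3.0, 0.5
    remainder = 0.5 * (np.sum(Yc ** 2) - np.sum(Ytc ** 2))
    for _ in range(5):
        bt = rng.standard_normal((X.shape[1], prob.d))
        pen = sum(prob.gammas[i] * np.linalg.norm(bt[c])
                  for i, c in enumerate(prob.group_cols))
        # Eq with observations in the original T-dim space
        obj_full = (0.5 * np.sum((Yc - Xc @ bt @ Vd.T) ** 2)
                    + lam * pen + alpha * np.sum((bt @ Vd.T) ** 2))
        # Eq in the reduced d-dim space
        obj_red = (0.5 * np.sum((Ytc - Xc @ bt) ** 2)
                   + lam * pen + alpha * np.sum(bt ** 2))
        assert obj_full == pytest.approx(obj_red + remainder,
                                         rel=1e-10)
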