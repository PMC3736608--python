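"""Linear NMF variants: recovery, monotonicity, reductions, constraints."""

import numpy as np
import pytest

from nmfkit.factorizations import (
    DataMatrix,
    FitOptions,
    VSMFConfig,
    _pseudo_inverse_rows,
    convex_nmf,
    nmf_multiplicative,
    nmf_nnls,
    orth_nmf,
    seminmf,
    sparse_nmf,
    vsmf,
    weighted_nmf,
)
from nmfkit.solvers import QPProblem, solve_nnqp


def monotone(trace, slack=1e-9):
    t = np.asarray(trace)
    return bool(np.all(np.diff(t) <= slack * np.maximum(np.abs(t[:-1]), 1e-12)))


def match_factors(A_hat, A_true):
    """Best column correlation after permutation matching (greedy)."""
    k = A_true.shape[1]
    corr = np.corrcoef(A_hat.T, A_true.T)[:k, k:]
    used, scores = set(), []
    for j in range(k):
        order = np.argsort(-corr[:, j])
        i = next(i for i in order if i not in used)
        used.add(i)
        scores.append(corr[i, j])
    return min(scores)


class TestDataMatrix:
    def test_mask_from_nan(self):
        d = DataMatrix.from_array([[1.0, np.nan], [2.0, 3.0]])
        assert d.mask.tolist() == [[1.0, 0.0], [1.0, 1.0]]
        assert d.sign_mode == "non-negative"
        assert d.has_missing

    def test_sign_mode_mixed(self):
        assert DataMatrix.from_array([[-1.0, 2.0]]).sign_mode == "mixed"


class TestStandardNMF:
    def test_rank1_exact(self):
        X = np.outer([1.0, 2.0], [3.0, 1.0])
        res = nmf_multiplicative(X, 1, FitOptions(max_iter=2000, tol=1e-15))
        assert res.objective < 1e-10

    def test_diagonal_full_rank(self):
        X = np.diag([1.0, 2.0, 3.0, 4.0])
        res = nmf_multiplicative(
            X, 4, FitOptions(max_iter=5000, tol=1e-16, n_restarts=4)
        )
        assert res.objective < 1e-8

    def test_multiplicative_monotone(self, rng):
        X = rng.random((20, 10))
        res = nmf_multiplicative(X, 3, FitOptions(max_iter=200))
        assert monotone(res.objective_trace)
        assert res.A.min() >= 0 and res.Y.min() >= 0

    def test_nnls_planted_recovery(self, rng):
        # separable planted factors (factor-specific rows / columns) make the
        # factorization identifiable up to permutation and scaling
        A0 = 0.05 * rng.random((10, 2))
        A0[:3, 0] += rng.random(3) + 1
        A0[3:6, 1] += rng.random(3) + 1
        Y0 = 0.05 * rng.random((2, 8))
        Y0[0, :4] += rng.random(4) + 1
        Y0[1, 4:] += rng.random(4) + 1
        X = A0 @ Y0
        res = nmf_nnls(X, 2, FitOptions(max_iter=500, tol=1e-12))
        assert np.linalg.norm(X - res.A @ res.Y) / np.linalg.norm(X) < 1e-6
        assert match_factors(res.A, A0) > 0.999

    def test_nnls_full_rank(self, rng):
        X = rng.random((6, 5)) + 0.1
        res = nmf_nnls(X, 5, FitOptions(max_iter=300, tol=1e-14))
        assert res.objective < 1e-8

    def test_nnls_deterministic(self, rng):
        X = rng.random((12, 9))
        a = nmf_nnls(X, 3, FitOptions(seed=7, max_iter=50))
        b = nmf_nnls(X, 3, FitOptions(seed=7, max_iter=50))
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.Y, b.Y)

    def test_negative_data_rejected(self):
        with pytest.raises(ValueError, match="seminmf"):
            nmf_nnls(np.array([[1.0, -1.0]]).T @ np.ones((1, 3)), 1)


class TestSemiNMF:
    def test_a_update_identity_coefficients(self, rng):
        """With Y = I the least-squares basis update returns A = X."""
        X = rng.standard_normal((6, 4))
        A = X @ _pseudo_inverse_rows(np.eye(4))
        np.testing.assert_allclose(A, X, atol=1e-6)

    def test_mixed_sign_recovery(self, rng):
        A0 = rng.standard_normal((12, 2))
        Y0 = rng.random((2, 9)) + 0.1
        X = A0 @ Y0
        res = seminmf(X, 2, "nnls", FitOptions(max_iter=500, tol=1e-13))
        assert np.linalg.norm(X - res.A @ res.Y) / np.linalg.norm(X) < 1e-6
        assert res.Y.min() >= 0

    def test_nnls_no_worse_than_mult(self, rng):
        X = rng.standard_normal((15, 10))
        o_nnls = seminmf(X, 3, "nnls", FitOptions(max_iter=300)).objective
        o_mult = seminmf(X, 3, "mult", FitOptions(max_iter=300)).objective
        assert o_nnls <= 1.05 * o_mult

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError, match="k"):
            seminmf(rng.standard_normal((8, 4)), 4)


class TestSparseNMF:
    def test_lambda0_matches_nnls(self, rng):
        X = rng.random((20, 10))
        o_sparse = sparse_nmf(
            X, 3, VSMFConfig(lambda_sparse=0.0), opts=FitOptions(max_iter=300)
        ).objective
        o_nnls = nmf_nnls(X, 3, FitOptions(max_iter=300)).objective
        assert abs(o_sparse - o_nnls) <= 1e-6 * max(1, o_nnls) + 1e-6

    def test_unit_norm_columns(self, rng):
        X = rng.random((15, 10))
        res = sparse_nmf(X, 3, VSMFConfig(lambda_sparse=0.5), opts=FitOptions())
        np.testing.assert_allclose(np.linalg.norm(res.A, axis=0), 1.0, atol=1e-8)

    def test_sparsity_monotone_in_lambda(self, rng):
        X = rng.random((20, 10))
        fracs = []
        for lam in [0.0, 0.1, 1.0, 10.0]:
            res = sparse_nmf(
                X, 3, VSMFConfig(lambda_sparse=lam), opts=FitOptions(max_iter=200)
            )
            fracs.append(float((res.Y == 0).mean()))
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_y_step_soft_threshold(self):
        """With orthonormal basis the sparse Y step is max(x - lambda, 0)."""
        sol = solve_nnqp(QPProblem(np.eye(2), 2.0 - np.array([3.0, 1.0])))
        np.testing.assert_allclose(sol.x, [1.0, 0.0], atol=1e-10)

    def test_kim_park_runs(self, rng):
        X = rng.random((12, 8))
        res = sparse_nmf(
            X,
            2,
            VSMFConfig(lambda_sparse=0.2, eta=0.1),
            variant="kim_park",
            opts=FitOptions(max_iter=100),
        )
        assert res.A.min() >= 0 and res.Y.min() >= 0
        # plain-l1 flag changes the model but stays non-negative
        res2 = sparse_nmf(
            X,
            2,
            VSMFConfig(lambda_sparse=0.2, eta=0.1, squared_l1=False),
            variant="kim_park",
            opts=FitOptions(max_iter=100),
        )
        assert res2.Y.min() >= 0


class TestVSMF:
    def test_zero_regularization_matches_standard_update(self, rng):
        X = rng.random((10, 8))
        A0, Y0 = rng.random((10, 3)), rng.random((3, 8))
        shared = dict(init="provided", A0=A0, Y0=Y0, max_iter=1, tol=1e-30)
        a = vsmf(X, 3, VSMFConfig(), "mult", FitOptions(**shared))
        b = nmf_multiplicative(X, 3, FitOptions(**shared))
        np.testing.assert_allclose(a.A, b.A, atol=1e-12)
        np.testing.assert_allclose(a.Y, b.Y, atol=1e-12)

    def test_exact_fixed_point(self, rng):
        A0 = rng.random((10, 2)) + 0.5
        Y0 = rng.random((2, 7)) + 0.5
        X = A0 @ Y0
        res = vsmf(
            X,
            2,
            VSMFConfig(),
            "mult",
            FitOptions(init="provided", A0=A0, Y0=Y0, max_iter=1, tol=1e-30),
        )
        np.testing.assert_allclose(res.A, A0, atol=1e-12)
        np.testing.assert_allclose(res.Y, Y0, atol=1e-12)

    def test_mixed_sign_pattern_recovery(self, rng):
        """Rising and falling planted temporal profiles are recovered from
        mixed-sign data with a sign-free basis (t1=0)."""
        t = np.linspace(0, 1, 16)
        rise, fall = t - 0.5, 0.5 - t
        A0 = np.column_stack([rise, fall])
        Y0 = np.vstack(
            [
                np.r_[rng.random(6) + 1, rng.random(6) * 0.1],
                np.r_[rng.random(6) * 0.1, rng.random(6) + 1],
            ]
        )
        X = A0 @ Y0 + 0.01 * rng.standard_normal((16, 12))
        res = vsmf(
            X,
            2,
            VSMFConfig(alpha1=0.01, lambda2=0.01, t1=False, t2=True),
            "active_set",
            FitOptions(max_iter=200, seed=3),
        )
        corr = np.abs(np.corrcoef(res.A.T, A0.T)[:2, 2:])
        # each planted profile matched by some recovered basis vector
        assert corr.max(axis=0).min() > 0.9

    def test_mult_rejects_sign_free(self, rng):
        with pytest.raises(ValueError, match="t1"):
            vsmf(rng.random((5, 4)), 2, VSMFConfig(t1=False), "mult")

    def test_active_set_monotone(self, rng):
        X = rng.random((15, 10))
        res = vsmf(
            X,
            3,
            VSMFConfig(alpha1=0.05, alpha2=0.05, lambda1=0.05, lambda2=0.05),
            "active_set",
            FitOptions(max_iter=100),
        )
        assert monotone(res.objective_trace)


class TestConvexNMF:
    def test_centroid_recovery(self, rng):
        c1, c2 = rng.random(8) * 2, rng.random(8) * 2 + 6
        pts = np.column_stack(
            [c1[:, None] + 0.05 * rng.standard_normal((8, 10)),
             c2[:, None] + 0.05 * rng.standard_normal((8, 10))]
        )
        res = convex_nmf(pts, 2, FitOptions(max_iter=500))
        A = res.A
        for c in (c1, c2):
            dists = np.linalg.norm(A - c[:, None], axis=0) / np.linalg.norm(c)
            assert dists.min() < 0.1

    def test_w_columns_sum_to_one(self, rng):
        res = convex_nmf(rng.standard_normal((6, 12)), 3, FitOptions(max_iter=50))
        np.testing.assert_allclose(res.extra["W"].sum(axis=0), 1.0, atol=1e-8)
        assert res.extra["W"].min() >= 0 and res.Y.min() >= 0

    def test_monotone_nonneg_input(self, rng):
        res = convex_nmf(rng.random((10, 14)), 3, FitOptions(max_iter=150))
        assert monotone(res.objective_trace)


class TestOrthNMF:
    def test_block_diagonal_orthogonality(self, rng):
        X = np.zeros((12, 10))
        X[:6, :5] = rng.random((6, 5)) + 0.5
        X[6:, 5:] = rng.random((6, 5)) + 0.5
        res = orth_nmf(X, 2, FitOptions(max_iter=2000, tol=1e-12))
        A = res.A / np.maximum(np.linalg.norm(res.A, axis=0), 1e-12)
        assert np.linalg.norm(A.T @ A - np.eye(2)) < 0.05

    def test_s_absorbs_scale(self, rng):
        X = rng.random((14, 11)) + 0.1
        r1 = orth_nmf(X, 3, FitOptions(max_iter=400, seed=2))
        r10 = orth_nmf(10 * X, 3, FitOptions(max_iter=400, seed=2))
        ratio = r10.extra["S"].sum() / r1.extra["S"].sum()
        assert 8 < ratio < 12
        assert abs(r10.extra["orth_dev_A"] - r1.extra["orth_dev_A"]) < 1e-3

    def test_monotone(self, rng):
        res = orth_nmf(rng.random((20, 15)), 3, FitOptions(max_iter=150))
        assert monotone(res.objective_trace)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            orth_nmf(np.array([[-1.0, 1.0], [1.0, 1.0]]), 1)


class TestWeightedNMF:
    def test_full_mask_matches_multiplicative(self, rng):
        X = rng.random((10, 8))
        A0, Y0 = rng.random((10, 3)), rng.random((3, 8))
        shared = dict(init="provided", A0=A0, Y0=Y0, max_iter=5, tol=1e-30)
        a = weighted_nmf(X, 3, FitOptions(**shared))
        b = nmf_multiplicative(X, 3, FitOptions(**shared))
        np.testing.assert_allclose(a.A, b.A, atol=1e-12)
        np.testing.assert_allclose(a.Y, b.Y, atol=1e-12)

    def test_rank1_completion(self, rng):
        a, y = rng.random(5) + 0.5, rng.random(5) + 0.5
        X = np.outer(a, y)
        true_val = X[2, 3]
        X[2, 3] = np.nan
        res = weighted_nmf(X, 1, FitOptions(max_iter=2000, tol=1e-14))
        assert abs(res.extra["X_imputed"][2, 3] - true_val) < 1e-3

    def test_masked_cells_ignored(self, rng):
        X = rng.random((8, 6))
        X[1, 1] = np.nan
        X2 = X.copy()
        d1, d2 = DataMatrix.from_array(X), DataMatrix.from_array(X2)
        d2.X[1, 1] = 99.0  # stored value under the mask must not matter
        r1 = weighted_nmf(d1, 2, FitOptions(max_iter=50))
        r2 = weighted_nmf(d2, 2, FitOptions(max_iter=50))
        np.testing.assert_array_equal(r1.A, r2.A)

    def test_fully_missing_column_warns(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.warns(UserWarning, match="unconstrained"):
            weighted_nmf(X, 1, FitOptions(max_iter=10))
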