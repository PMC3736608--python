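"""Clustering, rank selection, biclustering, feature extraction/selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmfkit.factorizations import FitOptions, nmf_nnls
from nmfkit.kernels import KernelSpec
from nmfkit.mining import (
    assign_clusters,
    bicluster,
    choose_best_k,
    dispersion_coefficient,
    extract_features_test,
    extract_features_train,
    select_features_entropy,
)
from nmfkit.synthetic import SyntheticSpec, generate_synthetic


class TestAssignClusters:
    def test_argmax_labels(self):
        res = assign_clusters([[0.9, 0.1], [0.1, 0.8]])
        assert res.labels.tolist() == [1, 2]

    def test_tie_goes_to_lowest_row(self):
        res = assign_clusters([[0.5], [0.5]])
        assert res.labels.tolist() == [1]

    def test_zero_column_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            res = assign_clusters([[0.0, 1.0], [0.0, 0.2]])
        assert res.labels[0] == 1

    def test_recovers_planted_clusters(self):
        from sklearn.metrics import adjusted_rand_score

        data, _, _, labels = generate_synthetic(SyntheticSpec(seed=11))
        res = nmf_nnls(data, 3, FitOptions(max_iter=200, seed=0))
        pred = assign_clusters(res.Y).labels
        assert adjusted_rand_score(labels, pred) > 0.95

    def test_scale_invariance(self, rng):
        Y = rng.random((3, 10))
        scales = rng.random(10) + 0.5
        a = assign_clusters(Y).labels
        b = assign_clusters(Y * scales).labels
        np.testing.assert_array_equal(a, b)


class TestDispersion:
    def test_binary_consensus_is_one(self):
        assert dispersion_coefficient(np.ones((5, 5))) == pytest.approx(1.0)

    def test_half_off_diagonal(self):
        n = 6
        C = np.full((n, n), 0.5)
        np.fill_diagonal(C, 1.0)
        assert dispersion_coefficient(C) == pytest.approx(n / n**2)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_bounds_and_binary_iff_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        C = rng.random((n, n))
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 1.0)
        rho = dispersion_coefficient(C)
        assert 0.0 <= rho <= 1.0
        binary = np.isin(C, [0.0, 1.0]).all()
        assert (rho == pytest.approx(1.0)) == bool(binary)


class TestChooseBestK:
    def test_recovers_planted_rank(self):
        data, _, _, _ = generate_synthetic(SyntheticSpec(m=40, n=24, k=3, seed=5))
        best_k, summaries = choose_best_k(
            data, [2, 3, 4, 5], runs=20, opts=FitOptions(max_iter=100)
        )
        assert best_k == 3
        assert summaries[3].dispersion == pytest.approx(1.0, abs=0.05)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            choose_best_k(np.ones((4, 4)), [])


class TestBicluster:
    def test_block_diagonal_exact_recovery(self, rng):
        # two expression blocks plus unexpressed (all-zero) feature rows, so
        # each basis column is cleanly bimodal and mean + 1 sd separates it
        X = np.zeros((24, 12))
        X[:8, :6] = 0.2 * rng.random((8, 6)) + 1
        X[8:16, 6:] = 0.2 * rng.random((8, 6)) + 1
        bics, _ = bicluster(X, 2, row_z=1.0, opts=FitOptions(max_iter=200, seed=0))
        got = sorted(
            (tuple(b.row_members.tolist()), tuple(b.col_members.tolist()))
            for b in bics
        )
        expected = sorted(
            [(tuple(range(8)), tuple(range(6))),
             (tuple(range(8, 16)), tuple(range(6, 12)))]
        )
        assert got == expected

    def test_huge_row_z_empties_rows(self, rng):
        X = rng.random((15, 10)) + 0.1
        with pytest.warns(UserWarning, match="empty"):
            bics, _ = bicluster(X, 2, row_z=1e6, opts=FitOptions(max_iter=50))
        assert all(b.row_members.size == 0 for b in bics)

    def test_columns_partition_samples(self, rng):
        X = rng.random((15, 10)) + 0.1
        bics, _ = bicluster(X, 3, opts=FitOptions(max_iter=50))
        cols = np.concatenate([b.col_members for b in bics])
        assert sorted(cols.tolist()) == list(range(10))


class TestFeatureExtraction:
    def test_shapes_and_signs(self):
        data, _, _, _ = generate_synthetic(
            SyntheticSpec(m=20, n=12, k=3, factor_specific_features=5, seed=2)
        )
        space = extract_features_train(data, 3, "nmf", FitOptions(max_iter=100))
        assert space.A.shape == (20, 3)
        assert space.Y_tr.shape == (3, 12)
        assert space.A.min() >= 0 and space.Y_tr.min() >= 0

    def test_exact_rank3_reconstruction(self):
        data, A, Y, _ = generate_synthetic(
            SyntheticSpec(m=24, n=15, k=3, factor_specific_features=6, seed=3)
        )
        space = extract_features_train(
            data, 3, "nmf", FitOptions(max_iter=500, tol=1e-13)
        )
        X = data.X
        rel = np.linalg.norm(X - space.A @ space.Y_tr) / np.linalg.norm(X)
        assert rel < 1e-5

    def test_deterministic(self):
        data, _, _, _ = generate_synthetic(SyntheticSpec(seed=4))
        a = extract_features_train(data, 3, "nmf", FitOptions(seed=9, max_iter=50))
        b = extract_features_train(data, 3, "nmf", FitOptions(seed=9, max_iter=50))
        np.testing.assert_array_equal(a.A, b.A)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="supported"):
            extract_features_train(np.ones((4, 4)), 2, "pca")

    def test_project_basis_gives_identity(self, rng):
        A = rng.random((12, 3)) + 0.1
        space = extract_features_train(
            A @ (rng.random((3, 8)) + 0.1), 3, "nmf", FitOptions(max_iter=300)
        )
        Y = extract_features_test(space, space.A)
        np.testing.assert_allclose(Y, np.eye(3), atol=1e-8)
        Y2 = extract_features_test(space, 2 * space.A)
        np.testing.assert_allclose(Y2, 2 * np.eye(3), atol=1e-8)

    def test_reprojection_consistency(self):
        data, _, _, _ = generate_synthetic(
            SyntheticSpec(m=20, n=12, factor_specific_features=6, seed=6)
        )
        space = extract_features_train(
            data, 3, "nmf", FitOptions(max_iter=400, tol=1e-12)
        )
        Y_uk = extract_features_test(space, data.X)
        obj_tr = np.linalg.norm(data.X - space.A @ space.Y_tr) ** 2
        obj_uk = np.linalg.norm(data.X - space.A @ Y_uk) ** 2
        assert obj_uk <= obj_tr + 1e-6

    def test_nonneg_column_space_zero_residual(self, rng):
        A = rng.random((10, 3)) + 0.1
        space = extract_features_train(
            A @ (rng.random((3, 7)) + 0.1), 3, "nmf", FitOptions(max_iter=300)
        )
        S = space.A @ (rng.random((3, 4)) + 0.1)
        Y = extract_features_test(space, S)
        assert np.linalg.norm(S - space.A @ Y) < 1e-6

    def test_kernel_space_projection(self):
        data, _, _, labels = generate_synthetic(
            SyntheticSpec(m=20, n=16, factor_specific_features=6, seed=7)
        )
        space = extract_features_train(
            data, 3, kernel=KernelSpec("rbf", sigma=5.0),
            opts=FitOptions(max_iter=100),
        )
        Y_uk = extract_features_test(space, data.X[:, :4])
        assert Y_uk.shape == (3, 4)
        assert Y_uk.min() >= 0


class TestEntropySelection:
    def test_one_hot_scores_one(self):
        sel = select_features_entropy(np.array([[1.0, 0.0, 0.0], [0.2, 0.2, 0.2]]))
        assert sel.score[0] == pytest.approx(1.0)
        assert sel.score[1] == pytest.approx(0.0, abs=1e-12)

    def test_planted_one_hot_rows_selected(self, rng):
        A = np.full((100, 4), 0.25)
        hot = rng.choice(100, size=10, replace=False)
        for i, r in enumerate(hot):
            A[r] = 0.0
            A[r, i % 4] = 1.0
        sel = select_features_entropy(A, threshold_sd=2.0)
        chosen = np.concatenate([v for v in sel.selected.values()])
        assert sorted(chosen.tolist()) == sorted(hot.tolist())

    def test_zero_rows_excluded(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0], [0.5, 0.5]])
        sel = select_features_entropy(A)
        assert sel.excluded_rows.tolist() == [1]
        assert np.isnan(sel.score[1])

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            select_features_entropy(np.ones((5, 1)))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_score_bounds(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((int(rng.integers(2, 20)), int(rng.integers(2, 6))))
        sel = select_features_entropy(A)
        s = sel.score[~np.isnan(sel.score)]
        assert np.all(s >= -1e-12) and np.all(s <= 1 + 1e-12)
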