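"""MMD block matrices, the generalized eigenproblem and the refinement loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ceda.datasets import DomainDataset, RunConfig
from ceda.jda import (
    MMDMatrixSet,
    _pooled_zscore_pair,
    build_conditional_mmd,
    build_marginal_mmd,
    centering_matrix,
    jda_iterate,
    solve_jda_eigenproblem,
)
from ceda.simulate import make_experiment

from .conftest import separable_domain


def outer_product_oracle(ns, nt):
    v = np.concatenate([np.full(ns, 1.0 / ns), np.full(nt, -1.0 / nt)])
    return np.outer(v, v)


class TestMarginalMMD:
    def test_smallest_case(self):
        np.testing.assert_array_equal(
            build_marginal_mmd(1, 1), [[1.0, -1.0], [-1.0, 1.0]]
        )

    def test_block_values_and_zero_sum(self):
        M = build_marginal_mmd(2, 3)
        assert np.allclose(M[:2, :2], 1 / 4)
        assert np.allclose(M[2:, 2:], 1 / 9)
        assert np.allclose(M[:2, 2:], -1 / 6)
        assert abs(M.sum()) < 1e-12

    @given(ns=st.integers(1, 40), nt=st.integers(1, 40))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_equals_outer_product_oracle(self, ns, nt):
        np.testing.assert_array_equal(
            build_marginal_mmd(ns, nt), outer_product_oracle(ns, nt)
        )

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            build_marginal_mmd(0, 3)


class TestConditionalMMD:
    def test_two_by_two_example(self):
        # source labels (1,2), target pseudo (1,2): class-1 matrix touches
        # stacked positions {0, 2} only, with the 1/-1 pattern.
        mats = build_conditional_mmd([1, 2], [1, 2], [1, 2])
        M1, M2 = mats
        expected1 = np.zeros((4, 4))
        expected1[np.ix_([0, 2], [0, 2])] = [[1, -1], [-1, 1]]
        expected2 = np.zeros((4, 4))
        expected2[np.ix_([1, 3], [1, 3])] = [[1, -1], [-1, 1]]
        np.testing.assert_array_equal(M1, expected1)
        np.testing.assert_array_equal(M2, expected2)

    def test_absent_class_gives_zero_matrix(self, caplog):
        mats = build_conditional_mmd([1, 2, 2], [1, 1], [1, 2])
        np.testing.assert_array_equal(mats[1], np.zeros((5, 5)))

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside the class set"):
            build_conditional_mmd([1, 3], [1, 1], [1, 2])

    @pytest.mark.parametrize("seed", range(8))
    def test_each_matrix_is_psd_rank_one_zero_sum(self, seed):
        r = np.random.default_rng(seed)
        ns, nt = r.integers(4, 20), r.integers(4, 20)
        ys = r.integers(1, 4, ns)
        yt = r.integers(1, 4, nt)
        classes = np.arange(1, 4)
        # guarantee every class present in both blocks
        ys[:3] = [1, 2, 3]
        yt[:3] = [1, 2, 3]
        for M in build_conditional_mmd(ys, yt, classes):
            np.testing.assert_array_equal(M, M.T)
            assert abs(M.sum()) < 1e-12
            w = np.linalg.eigvalsh(M)
            assert w.min() >= -1e-12
            assert np.sum(w > 1e-12) <= 1

    def test_total_is_symmetric_psd(self):
        mset = MMDMatrixSet.from_labels([1, 1, 2], [2, 1], [1, 2])
        T = mset.total()
        np.testing.assert_allclose(T, T.T)
        assert np.linalg.eigvalsh(T).min() >= -1e-12
        assert mset.class_counts == {1: (2, 1), 2: (1, 1)}


class TestCenteringMatrix:
    def test_small_cases(self):
        np.testing.assert_array_equal(centering_matrix(1), [[0.0]])
        np.testing.assert_allclose(
            centering_matrix(2), [[0.5, -0.5], [-0.5, 0.5]]
        )

    def test_idempotent_and_annihilates_ones(self):
        H = centering_matrix(7)
        np.testing.assert_allclose(H @ H, H, atol=1e-12)
        np.testing.assert_allclose(H @ np.ones(7), np.zeros(7), atol=1e-12)


def eigen_residual(X, M, lam, A, w):
    lhs = X @ (0.5 * (M + M.T)) @ X.T + lam * np.eye(X.shape[0])
    Xc = X - X.mean(axis=1, keepdims=True)
    rhs = Xc @ Xc.T
    worst = 0.0
    for j in range(A.shape[1]):
        num = np.linalg.norm(lhs @ A[:, j] - w[j] * rhs @ A[:, j])
        den = np.linalg.norm(lhs @ A[:, j])
        worst = max(worst, num / den)
    return worst


def random_solve_instance(seed, d=6, ns=25, nt=20):
    r = np.random.default_rng(seed)
    X = np.vstack(
        [r.standard_normal((ns, d)), r.standard_normal((nt, d)) + 0.5]
    ).T
    ys = 1 + (np.arange(ns) % 2)
    yt = 1 + (np.arange(nt) % 2)
    M = build_marginal_mmd(ns, nt)
    for Mc in build_conditional_mmd(ys, yt, [1, 2]):
        M = M + Mc
    return X, M


class TestEigenproblem:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("k", [1, 3])
    def test_residual_bound(self, seed, k):
        X, M = random_solve_instance(seed)
        A, w = solve_jda_eigenproblem(X, M, lam=0.5, k=k)
        assert eigen_residual(X, M, 0.5, A, w) <= 1e-8
        assert np.all(np.diff(w) >= -1e-12)  # ascending

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_mmd_reduces_to_principal_components(self, seed):
        """With M = 0 the problem is lam a = X H X' a phi: the smallest-phi
        subspace is spanned by the leading principal axes of the centered
        data."""
        import scipy.linalg

        X, _ = random_solve_instance(seed, d=8)
        k = 3
        A, _ = solve_jda_eigenproblem(X, np.zeros((X.shape[1],) * 2), lam=1.0, k=k)
        Xc = X - X.mean(axis=1, keepdims=True)
        U, _, _ = np.linalg.svd(Xc, full_matrices=False)
        angles = scipy.linalg.subspace_angles(A, U[:, :k])
        assert np.max(angles) <= 1e-6

    def test_deterministic_eigenvalues(self):
        X, M = random_solve_instance(42)
        _, w1 = solve_jda_eigenproblem(X, M, 2.0, 4)
        _, w2 = solve_jda_eigenproblem(X, M, 2.0, 4)
        np.testing.assert_array_equal(w1, w2)

    def test_large_lambda_dominates_linearly(self):
        X, M = random_solve_instance(3)
        _, w_lo = solve_jda_eigenproblem(X, M, 1e4, 3)
        _, w_hi = solve_jda_eigenproblem(X, M, 1e8, 3)
        np.testing.assert_allclose(w_hi / w_lo, 1e4, rtol=1e-2)

    def test_k_exceeding_dimension_rejected(self):
        X, M = random_solve_instance(0)
        with pytest.raises(ValueError):
            solve_jda_eigenproblem(X, M, 1.0, k=X.shape[0] + 1)


class TestJdaIterate:
    def test_single_iteration_history(self):
        src = separable_domain(0)
        tgt = separable_domain(1, tag="target")
        cfg = RunConfig(k=2, lam=1.0, max_iters=1)
        res = jda_iterate(src, tgt.without_labels(), cfg, np.ones(tgt.n_samples, int))
        assert res.iterations_run == 1 and len(res.history) == 1

    def test_embedding_consistent_with_projection(self):
        src = separable_domain(2)
        tgt = separable_domain(3, tag="target")
        cfg = RunConfig(k=2, lam=1.0, max_iters=2, normalize=False)
        res = jda_iterate(src, tgt.without_labels(), cfg, np.ones(tgt.n_samples, int))
        X = np.vstack([src.features, tgt.features]).T
        np.testing.assert_allclose(res.embedding_z, res.matrix_a.T @ X, atol=1e-10)
        assert res.eigenvalues.shape == (2,)

    def test_identical_separable_domains_recover_labels(self):
        src = separable_domain(4)
        tgt = DomainDataset(src.features.copy(), domain_tag="target")
        cfg = RunConfig(k=2, lam=1.0, max_iters=10)
        # start from deliberately poor pseudo-labels
        initial = np.ones(tgt.n_samples, dtype=np.int64)
        res = jda_iterate(src, tgt, cfg, initial)
        np.testing.assert_array_equal(res.pseudo_labels, src.labels)
        assert res.iterations_run <= 3
        assert res.history[-1]["pseudo_label_changes"] == 0

    def test_target_reordering_equivariance(self):
        src = separable_domain(5)
        r = np.random.default_rng(0)
        Xt = r.standard_normal((30, src.n_features)) + 2.0
        tgt = DomainDataset(Xt, domain_tag="target")
        perm = r.permutation(30)
        tgt_perm = DomainDataset(Xt[perm], domain_tag="target")
        cfg = RunConfig(k=2, lam=1.0, max_iters=3)
        init = np.ones(30, dtype=np.int64)
        res = jda_iterate(src, tgt, cfg, init)
        res_p = jda_iterate(src, tgt_perm, cfg, init[perm])
        np.testing.assert_array_equal(res.pseudo_labels[perm], res_p.pseudo_labels)

    def test_embedding_mmd_beats_random_projection(self):
        """The learned projection reduces the marginal discrepancy more than
        a random projection of matched column scale, on the fixed-overlap
        design, in at least 16/20 seeded runs."""
        better = 0
        for seed in range(20):
            src, tgt = make_experiment("overlap", "a", seed)
            Xs, Xt = _pooled_zscore_pair(src.features, tgt.features)
            src_n = DomainDataset(Xs, src.labels)
            tgt_n = DomainDataset(Xt)
            cfg = RunConfig(k=2, lam=1.0, max_iters=5, normalize=False)
            init = np.ones(tgt_n.n_samples, dtype=np.int64)
            res = jda_iterate(src_n, tgt_n, cfg, init)
            X = np.vstack([Xs, Xt]).T
            m0 = build_marginal_mmd(len(Xs), len(Xt))
            quad = X @ m0 @ X.T
            learned = np.trace(res.matrix_a.T @ quad @ res.matrix_a)
            R = np.random.default_rng(1000 + seed).standard_normal(res.matrix_a.shape)
            R *= np.linalg.norm(res.matrix_a, axis=0) / np.linalg.norm(R, axis=0)
            random_val = np.trace(R.T @ quad @ R)
            better += learned < random_val
        assert better >= 16

    def test_requires_source_labels(self):
        src = separable_domain(6)
        tgt = separable_domain(7, tag="target")
        with pytest.raises(ValueError, match="labels"):
            jda_iterate(
                tgt.without_labels(), tgt.without_labels(), RunConfig(), np.ones(80, int)
            )
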