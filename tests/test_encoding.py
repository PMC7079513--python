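"""Codebook learning, BoW/LLC coding, pooling, baselines."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

from histosurv.encoding import (
    aggregate_statistic,
    cellular_voting,
    encode_bow,
    encode_llc,
    learn_codebook,
    pool,
)


def llc_qp_oracle(x, B, k):
    """Generic equality-constrained QP solve of the LLC subproblem.

    Textbook KKT route: minimize ||x - B_k c||^2 s.t. 1'c = 1 by solving
    the augmented system [[2 B_k'B_k, 1], [1', 0]] [c; nu] = [2 B_k'x; 1]
    with a least-squares solver. Works on the raw (uncentered) quadratic,
    independent of the centered-Gram shortcut used by the implementation.
    """
    d2 = ((B - x[:, None]) ** 2).sum(axis=0)
    nn = np.argsort(d2, kind="stable")[:k]
    Bk = B[:, nn]
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = 2 * Bk.T @ Bk
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    rhs = np.concatenate([2 * Bk.T @ x, [1.0]])
    sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
    full = np.zeros(B.shape[1])
    full[nn] = sol[:k]
    return full


def llc_slsqp_oracle(x, B, k):
    """Iterative constrained-optimizer route (SLSQP); converges to ~1e-7."""
    d2 = ((B - x[:, None]) ** 2).sum(axis=0)
    nn = np.argsort(d2, kind="stable")[:k]
    Bk = B[:, nn]
    res = minimize(
        lambda c: ((x - Bk @ c) ** 2).sum(),
        np.full(k, 1.0 / k),
        jac=lambda c: 2 * Bk.T @ (Bk @ c - x),
        constraints=[{"type": "eq", "fun": lambda c: c.sum() - 1.0,
                      "jac": lambda c: np.ones_like(c)}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    full = np.zeros(B.shape[1])
    full[nn] = res.x
    return full


class TestCodebook:
    def test_codewords_reproduce_distinct_points(self):
        rng = np.random.default_rng(0)
        X = rng.random((4, 6)) * 10
        cb = learn_codebook(X, M=6, seed=0)
        # zero-inertia solution: every point is its own codeword
        assert cb.inertia == pytest.approx(0.0, abs=1e-9)
        d = np.linalg.norm(X[:, :, None] - cb.B[:, None, :], axis=0)
        assert np.allclose(d.min(axis=1), 0.0, atol=1e-8)

    def test_default_size_is_256(self):
        rng = np.random.default_rng(1)
        X = rng.random((3, 600))
        assert learn_codebook(X, seed=0).n_codewords == 256

    def test_recovers_generator_cluster_means(self, clustered_descriptors):
        X, labels = clustered_descriptors
        cb = learn_codebook(X, M=8, seed=0)
        for k in range(8):
            mean_k = X[:, labels == k].mean(axis=1)
            nearest = np.linalg.norm(cb.B - mean_k[:, None], axis=0).min()
            assert nearest < 0.1

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            learn_codebook(np.zeros((2, 5)), M=10)


class TestBow:
    def test_exact_codeword_is_one_hot(self):
        B = np.array([[0.0, 1.0, 2.0]])
        C = encode_bow(np.array([[1.0]]), B).C
        assert np.array_equal(C[:, 0], [0, 1, 0])

    def test_total_mass_equals_cell_count(self):
        rng = np.random.default_rng(0)
        C = encode_bow(rng.random((4, 30)), rng.random((4, 7))).C
        assert C.sum() == 30

    def test_tie_goes_to_lowest_index(self):
        B = np.array([[0.0, 1.0]])
        C = encode_bow(np.array([[0.5]]), B).C
        assert np.array_equal(C[:, 0], [1, 0])


class TestLLC:
    def test_k1_equals_hard_vq(self):
        rng = np.random.default_rng(0)
        X, B = rng.random((5, 40)), rng.random((5, 12))
        assert np.array_equal(encode_llc(X, B, k=1).C, encode_bow(X, B).C)

    def test_hand_computed_midpoint_code(self):
        # D=1, x=0.5 between codewords 0 and 1 -> equal weights
        C = encode_llc(np.array([[0.5]]), np.array([[0.0, 1.0]]), k=2).C
        assert np.allclose(C[:, 0], [0.5, 0.5], atol=1e-10)

    def test_exact_codeword_hit_interpolates_itself(self):
        rng = np.random.default_rng(1)
        B = rng.random((3, 8))
        x = B[:, [4]].copy()
        C = encode_llc(x, B, k=3).C
        assert C[4, 0] == pytest.approx(1.0, abs=1e-6)
        recon = B @ C[:, 0]
        assert np.allclose(recon, x[:, 0], atol=1e-6)

    def test_column_sums_are_one(self):
        rng = np.random.default_rng(2)
        C = encode_llc(rng.random((6, 50)), rng.random((6, 20)), k=5).C
        assert np.allclose(C.sum(axis=0), 1.0, atol=1e-10)

    def test_reconstruction_never_worse_than_vq(self):
        rng = np.random.default_rng(3)
        X, B = rng.random((4, 25)), rng.random((4, 10))
        Cl = encode_llc(X, B, k=4).C
        Cb = encode_bow(X, B).C
        err_llc = np.linalg.norm(X - B @ Cl, axis=0)
        err_vq = np.linalg.norm(X - B @ Cb, axis=0)
        assert (err_llc <= err_vq + 1e-9).all()

    def test_agrees_with_generic_qp_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.standard_normal(5)
            B = rng.standard_normal((5, 20))
            mine = encode_llc(x[:, None], B, k=5).C[:, 0]
            assert np.abs(mine - llc_qp_oracle(x, B, 5)).max() < 1e-8
            # second, fully iterative route at its own precision
            assert np.abs(mine - llc_slsqp_oracle(x, B, 5)).max() < 1e-6

    def test_duplicate_codewords_do_not_crash(self):
        B = np.ones((3, 4))  # fully degenerate codebook
        C = encode_llc(np.random.default_rng(0).random((3, 2)), B, k=3).C
        assert np.allclose(C.sum(axis=0), 1.0)
        assert np.isfinite(C).all()


class TestPooling:
    def test_single_cell_is_normalized_code(self):
        C = np.array([[0.3], [0.4]])
        f = pool(C, "sum").f
        assert np.allclose(f, C[:, 0] / np.linalg.norm(C[:, 0]))

    def test_sum_of_one_hots_is_histogram(self):
        rng = np.random.default_rng(0)
        Cb = encode_bow(rng.random((3, 40)), rng.random((3, 5)))
        f = pool(Cb, "sum", normalize=False).f
        assert f.sum() == 40
        assert np.array_equal(f, Cb.C.sum(axis=1))

    def test_max_pooling_hand_example(self):
        C = np.array([[0.2, 0.5], [0.8, 0.5]])
        f = pool(C, "max").f
        assert np.allclose(f, np.array([0.5, 0.8]) / np.sqrt(0.89))

    def test_sum_pooling_permutation_invariant(self):
        rng = np.random.default_rng(1)
        C = rng.random((6, 15))
        perm = rng.permutation(15)
        assert np.allclose(pool(C, "sum").f, pool(C[:, perm], "sum").f)

    def test_zero_vector_normalization_warns(self):
        with pytest.warns(UserWarning):
            f = pool(np.zeros((3, 2)), "sum").f
        assert np.array_equal(f, np.zeros(3))


class TestBaselines:
    def test_aggregate_statistic_dimension(self):
        X = np.random.default_rng(0).random((512, 10))
        assert len(aggregate_statistic(X).f) == 1536

    def test_identical_columns_zero_std(self):
        X = np.tile(np.arange(4.0)[:, None], (1, 6))
        f = aggregate_statistic(X).f
        assert np.array_equal(f[:4], np.arange(4.0))  # means
        assert np.array_equal(f[4:8], np.arange(4.0))  # medians
        assert np.allclose(f[8:], 0.0)  # stds

    def test_population_std_convention(self):
        X = np.array([[1.0, 3.0], [2.0, 2.0]])
        assert np.allclose(aggregate_statistic(X).f, [2, 2, 2, 2, 1, 0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_cellular_voting_is_mean(self, scores):
        assert cellular_voting(scores) == pytest.approx(np.mean(scores))

    def test_voting_empty_rejected(self):
        with pytest.raises(ValueError):
            cellular_voting([])
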