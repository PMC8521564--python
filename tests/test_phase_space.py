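"""Embedding, fuzzy c-means, and fuzzy recurrence plot construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recureig import (
    EmbeddingConfig,
    build_frp,
    embed,
    fcm_partition,
    frp_from_partition,
)


class TestEmbed:
    @pytest.mark.parametrize(
        "series, m, tau, expected",
        [
            ([1, 2, 3, 4, 5], 2, 1, [[1, 2], [2, 3], [3, 4], [4, 5]]),
            ([1, 2, 3, 4, 5, 6], 3, 2, [[1, 3, 5], [2, 4, 6]]),
            ([1, 2, 3], 1, 1, [[1], [2], [3]]),
        ],
    )
    def test_delay_coordinates(self, series, m, tau, expected):
        X = embed(series, EmbeddingConfig(m, tau))
        np.testing.assert_array_equal(X, np.array(expected, dtype=float))

    def test_eigenworm_sized_series(self, rng):
        X = embed(rng.normal(size=900), EmbeddingConfig(4, 1))
        assert X.shape == (897, 4)

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="N >= 7"):
            embed([1, 2, 3], EmbeddingConfig(m=4, tau=2))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            embed([1.0, np.nan, 2.0], EmbeddingConfig(1, 1))

    @given(
        n=st.integers(5, 200),
        m=st.integers(1, 6),
        tau=st.integers(1, 5),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_shape_law(self, n, m, tau):
        """M = N - (m-1)*tau, and each row is a delayed slice of the series."""
        if n < (m - 1) * tau + 1:
            return
        t = np.arange(n, dtype=float)
        X = embed(t, EmbeddingConfig(m, tau))
        assert X.shape == (n - (m - 1) * tau, m)
        i, j = X.shape[0] - 1, m - 1
        assert X[i, j] == t[i + j * tau]


def _fcm_oracle(X, c, f=2.0, iters=500):
    """Naive alternating-optimization FCM, scalar loops, crisp-on-zero."""
    M = len(X)
    U = np.full((M, c), 1.0 / c)
    U[: M // 2, 0] += 0.1  # deterministic symmetry-breaking init
    U /= U.sum(axis=1, keepdims=True)
    V = np.zeros((c, X.shape[1]))
    for _ in range(iters):
        for j in range(c):
            w = U[:, j] ** f
            V[j] = (w[:, None] * X).sum(axis=0) / w.sum()
        for i in range(M):
            d = np.array([np.sum((X[i] - V[j]) ** 2) for j in range(c)])
            if np.any(d == 0):
                U[i] = 0.0
                U[i, int(np.argmax(d == 0))] = 1.0
            else:
                for j in range(c):
                    U[i, j] = 1.0 / np.sum((d[j] / d) ** (1.0 / (f - 1.0)))
    return U, V


class TestFCM:
    def test_single_cluster_memberships_are_one(self, rng):
        X = rng.normal(size=(20, 3))
        part = fcm_partition(X, c=1)
        np.testing.assert_array_equal(part.U, np.ones((20, 1)))

    def test_two_well_separated_groups_match_oracle(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        part = fcm_partition(X, c=2, seed=3)
        U_ref, V_ref = _fcm_oracle(X, c=2)
        order = np.argsort(part.V.ravel())
        ref_order = np.argsort(V_ref.ravel())
        np.testing.assert_allclose(
            np.sort(part.V.ravel()), np.sort(V_ref.ravel()), atol=1e-6
        )
        np.testing.assert_allclose(
            part.U[:, order], U_ref[:, ref_order], atol=1e-5
        )
        # points at 0 belong almost fully to the center near 0
        low = order[0]
        assert part.U[0, low] > 0.99 and part.U[1, low] > 0.99

    def test_row_sums_and_range(self, rng):
        X = rng.normal(size=(40, 2))
        part = fcm_partition(X, c=4, seed=0)
        np.testing.assert_allclose(part.U.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(part.U >= 0) and np.all(part.U <= 1)

    def test_objective_trace_non_increasing(self, rng):
        X = rng.normal(size=(60, 3))
        part = fcm_partition(X, c=3, seed=1)
        trace = np.array(part.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10 * trace[0])

    def test_fixed_seed_is_bitwise_deterministic(self, rng):
        X = rng.normal(size=(30, 2))
        a = fcm_partition(X, c=3, seed=9)
        b = fcm_partition(X, c=3, seed=9)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_too_many_clusters_errors(self):
        with pytest.raises(ValueError, match="1 <= c <= M"):
            fcm_partition(np.zeros((3, 1)), c=4)

    def test_degenerate_input_warns_and_converges(self):
        X = np.ones((10, 2))
        with pytest.warns(RuntimeWarning, match="identical"):
            part = fcm_partition(X, c=3, seed=0)
        assert part.converged
        np.testing.assert_allclose(part.U.sum(axis=1), 1.0)


def _maxmin_oracle(U):
    M, c = U.shape
    R = np.zeros((M, M))
    for i in range(M):
        for k in range(M):
            R[i, k] = max(min(U[i, j], U[k, j]) for j in range(c))
    np.fill_diagonal(R, 1.0)
    return R


class TestFRP:
    def test_hand_composed_pair(self):
        U = np.array([[0.8, 0.2], [0.3, 0.7]])
        R = frp_from_partition(U)
        assert R[0, 1] == pytest.approx(0.3)
        assert R[1, 0] == pytest.approx(0.3)

    def test_crisp_memberships_give_binary_plot(self):
        U = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        R = frp_from_partition(U)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_array_equal(R, expected)

    def test_reflexivity_overrides_composed_self_value(self):
        U = np.array([[0.6, 0.4], [0.5, 0.5]])
        R = frp_from_partition(U)
        # composed self-similarity would be 0.6, but the diagonal is 1
        np.testing.assert_array_equal(np.diag(R), 1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            M = rng.integers(2, 13)
            c = rng.integers(1, 5)
            U = rng.random((M, c))
            np.testing.assert_array_equal(frp_from_partition(U), _maxmin_oracle(U))

    def test_invariant_under_cluster_column_permutation(self, rng):
        U = rng.random((15, 4))
        perm = rng.permutation(4)
        np.testing.assert_array_equal(
            frp_from_partition(U), frp_from_partition(U[:, perm])
        )

    def test_symmetry_unit_diagonal_and_range(self, rng):
        U = rng.random((30, 3))
        U /= U.sum(axis=1, keepdims=True)
        R = frp_from_partition(U)
        np.testing.assert_array_equal(R, R.T)
        np.testing.assert_array_equal(np.diag(R), 1.0)
        assert np.all((R >= 0) & (R <= 1))

    def test_rejects_out_of_range_memberships(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            frp_from_partition(np.array([[1.2, -0.2]]))


class TestBuildFRP:
    def test_shape_from_embedding(self, sine_series):
        R = build_frp(sine_series, EmbeddingConfig(4, 1), c=3, seed=0)
        assert R.shape == (297, 297)

    def test_constant_series_is_fully_recurrent(self):
        with pytest.warns(RuntimeWarning):
            R = build_frp(np.full(50, 2.5), EmbeddingConfig(2, 1), c=3, seed=0)
        np.testing.assert_array_equal(R, 1.0)

    def test_errors_carry_stage_names(self):
        with pytest.raises(ValueError, match="embedding"):
            build_frp([1.0, 2.0], EmbeddingConfig(4, 1), c=3)
        with pytest.raises(ValueError, match="clustering"):
            build_frp(np.arange(10.0), EmbeddingConfig(2, 1), c=50)
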