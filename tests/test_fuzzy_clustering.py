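import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from veneermatch.exceptions import DegenerateDataError, ParameterError
from veneermatch.fuzzy_clustering import (
    FuzzyPartition,
    cluster_lists_from_frame,
    fcm_cost,
    fcm_fit,
    partition_frame,
    rank_and_split,
)


def two_blobs(rng, n_per=15, sep=20.0):
    a = rng.normal(0.0, 0.5, (n_per, 3))
    b = rng.normal(sep, 0.5, (n_per, 3))
    return np.vstack([a, b])


def reference_fcm(X, U0, m=2.0, tol=1e-12, max_iter=500):
    """Deliberately plain loop-based alternating optimisation used as an
    independent cross-check of the vectorised implementation."""
    N, d = X.shape
    c = U0.shape[1]
    U = U0 / U0.sum(axis=1, keepdims=True)
    prev = None
    for _ in range(max_iter):
        V = np.zeros((c, d))
        for j in range(c):
            w = U[:, j] ** m
            V[j] = (w[:, None] * X).sum(axis=0) / w.sum()
        D2 = np.zeros((N, c))
        for i in range(N):
            for j in range(c):
                diff = X[i] - V[j]
                D2[i, j] = diff @ diff
        Unew = np.zeros_like(U)
        for i in range(N):
            zeros = np.flatnonzero(D2[i] == 0)
            if len(zeros):
                Unew[i, zeros] = 1.0 / len(zeros)
                continue
            for j in range(c):
                Unew[i, j] = 1.0 / np.sum((D2[i, j] / D2[i]) ** (1.0 / (m - 1.0)))
        U = Unew
        cost = float(np.sum(U**m * D2))
        if prev is not None and abs(prev - cost) < tol:
            break
        prev = cost
    return cost


class TestFcmCost:
    def test_coincident_points_zero_cost(self):
        X = np.zeros((4, 3))
        U = np.ones((4, 1))
        V = np.zeros((1, 3))
        assert fcm_cost(X, U, V) == 0.0

    def test_single_point_distance_two(self):
        X = np.array([[2.0, 0.0, 0.0]])
        U = np.array([[1.0]])
        V = np.array([[0.0, 0.0, 0.0]])
        assert fcm_cost(X, U, V) == pytest.approx(4.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(5, 2))
        U = rng.random((5, 3))
        U /= U.sum(axis=1, keepdims=True)
        V = rng.normal(size=(3, 2))
        m = 2.0
        oracle = 0.0
        for i in range(5):
            for j in range(3):
                oracle += U[i, j] ** m * np.sum((X[i] - V[j]) ** 2)
        assert fcm_cost(X, U, V, m) == pytest.approx(oracle, rel=1e-12)

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ParameterError):
            fcm_cost(np.zeros((2, 3)), np.ones((2, 1)) / 1, np.zeros((1, 3)), m=1.0)


class TestFcmFit:
    def test_separated_blobs_confident_memberships(self, rng):
        X = two_blobs(rng)
        part = fcm_fit(X, n_clusters=2, seed=0)
        max_u = part.memberships.max(axis=1)
        assert np.all(max_u > 0.99)
        # both blobs recovered: centroids near 0 and near 20
        centers = np.sort(part.centroids[:, 0])
        assert centers[0] == pytest.approx(0.0, abs=0.5)
        assert centers[1] == pytest.approx(20.0, abs=0.5)

    def test_zero_distance_rule(self):
        X = np.array([[0.0, 0, 0], [10.0, 0, 0], [10.0, 0.01, 0], [5.0, 5, 0]])
        part = fcm_fit(X, n_clusters=2, seed=1, max_iter=50)
        # a point exactly on a centroid would get membership 1; emulate by
        # evaluating the update at engineered distances instead
        from veneermatch.fuzzy_clustering import _update_memberships

        d2 = np.array([[0.0, 4.0]])
        np.testing.assert_array_equal(_update_memberships(d2, 2.0), [[1.0, 0.0]])
        assert part.converged

    def test_rows_sum_to_one_and_cost_monotone(self, rng):
        X = rng.normal(size=(30, 3))
        part = fcm_fit(X, n_clusters=4, seed=2)
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-9)
        diffs = np.diff(part.cost_trajectory)
        assert np.all(diffs <= 1e-12)

    def test_stationarity_at_convergence(self, rng):
        """One extra update pair changes the cost only marginally."""
        X = rng.normal(size=(30, 3))
        part = fcm_fit(X, n_clusters=3, seed=3, tol=1e-10, max_iter=500)
        extra = fcm_fit(
            X, n_clusters=3, init_memberships=part.memberships, max_iter=1, tol=0.0
        )
        assert abs(extra.final_cost - part.final_cost) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_cost_matches_independent_reference(self, seed):
        """Vectorised fit agrees with a plain loop-based reference started
        from the same initial membership matrix, on 30-point instances."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 3)) + rng.integers(0, 3, 30)[:, None] * 2.0
        U0 = np.random.default_rng(seed + 100).random((30, 4))
        part = fcm_fit(
            X, n_clusters=4, init_memberships=U0, tol=1e-12, max_iter=500
        )
        ref_cost = reference_fcm(X, U0, m=2.0)
        assert part.final_cost == pytest.approx(ref_cost, abs=1e-6)

    def test_hard_limit_small_m(self, rng):
        X = two_blobs(rng)
        part = fcm_fit(X, n_clusters=2, m=1.05, seed=4)
        assert np.all(part.memberships.max(axis=1) > 0.999)

    def test_uniform_limit_large_m(self, rng):
        X = two_blobs(rng)
        part = fcm_fit(X, n_clusters=2, m=50.0, seed=5)
        np.testing.assert_allclose(part.memberships, 0.5, atol=0.01)

    def test_centroids_inside_data_box(self, rng):
        X = rng.uniform(-3, 3, (40, 3))
        part = fcm_fit(X, n_clusters=5, seed=6)
        assert np.all(part.centroids >= X.min(axis=0) - 1e-9)
        assert np.all(part.centroids <= X.max(axis=0) + 1e-9)

    def test_row_permutation_invariance(self, rng):
        X = two_blobs(rng, n_per=20)
        part = fcm_fit(X, n_clusters=2, seed=7, tol=1e-12)
        perm = rng.permutation(len(X))
        part2 = fcm_fit(X[perm], n_clusters=2, seed=8, tol=1e-12)
        got = np.sort(part2.centroids[:, 0])
        want = np.sort(part.centroids[:, 0])
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            fcm_fit(np.ones((10, 3)), n_clusters=2, seed=0)

    def test_parameter_validation(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ParameterError):
            fcm_fit(X, n_clusters=1)
        with pytest.raises(ParameterError):
            fcm_fit(X, n_clusters=10)
        with pytest.raises(ParameterError):
            fcm_fit(X, n_clusters=2, m=1.0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(25, 3))
        a = fcm_fit(X, n_clusters=3, seed=42)
        b = fcm_fit(X, n_clusters=3, seed=42)
        np.testing.assert_array_equal(a.memberships, b.memberships)
        assert a.cost_trajectory == b.cost_trajectory


class TestRankAndSplit:
    def make_partition(self, U):
        U = np.asarray(U, dtype=float)
        return FuzzyPartition(
            memberships=U,
            centroids=np.zeros((U.shape[1], 3)),
            fuzzifier=2.0,
            cost_trajectory=[0.0],
            converged=True,
            seed=None,
            n_iter=1,
        )

    def test_confident_partition_has_empty_fuzzy_regions(self):
        U = [[0.95, 0.05], [0.92, 0.08], [0.03, 0.97]]
        lists = rank_and_split(self.make_partition(U), ["a", "b", "c"])
        assert all(cl.fuzzy_region == [] for cl in lists)
        assert lists[0].ordered_specimens == ["a", "b"]
        assert lists[1].ordered_specimens == ["c"]

    def test_low_membership_lands_in_fuzzy_region(self):
        U = [[0.4, 0.35, 0.25], [0.9, 0.05, 0.05], [0.8, 0.1, 0.1]]
        lists = rank_and_split(self.make_partition(U), ["low", "hi1", "hi2"])
        assert lists[0].fuzzy_region == ["low"]
        assert lists[0].unique_region == ["hi1", "hi2"]

    def test_ordering_matches_sort_oracle(self, rng):
        U = rng.random((20, 3))
        U /= U.sum(axis=1, keepdims=True)
        ids = [f"s{i:02d}" for i in range(20)]
        lists = rank_and_split(self.make_partition(U), ids)
        assigned = np.argmax(U, axis=1)
        max_u = U[np.arange(20), assigned]
        for cl in lists:
            members = [ids[i] for i in np.flatnonzero(assigned == cl.cluster_index)]
            oracle = sorted(members, key=lambda s: (-max_u[ids.index(s)], s))
            assert cl.ordered_specimens == oracle
            assert np.all(np.diff(cl.memberships) <= 1e-12)
            assert cl.unique_region + cl.fuzzy_region == cl.ordered_specimens

    def test_distance_ordered_fuzzy_region(self):
        """In distance mode, fuzzy-region members are re-ordered nearest
        first to the assigned centroid; the unique region keeps its
        membership ordering."""
        U = np.array([
            [0.8, 0.1, 0.1],   # a: unique in cluster 0
            [0.2, 0.45, 0.35],  # b: fuzzy, assigned cluster 1
            [0.3, 0.40, 0.30],  # c: fuzzy, assigned cluster 1
            [0.1, 0.8, 0.1],   # d: unique in cluster 1
        ])
        part = self.make_partition(U)
        part.centroids = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
        X = np.array([[0.0, 0, 0], [3.0, 0, 0], [1.5, 0, 0], [1.1, 0, 0]])
        ids = ["a", "b", "c", "d"]
        lists = rank_and_split(part, ids, fuzzy_order="distance", features=X)
        cl1 = lists[1]
        assert cl1.unique_region == ["d"]
        # fuzzy members b (dist 2.0) and c (dist 0.5): nearest first,
        # overriding the membership order (b 0.45 > c 0.40)
        assert cl1.fuzzy_region == ["c", "b"]
        assert cl1.ordered_specimens == ["d", "c", "b"]
        with pytest.raises(ParameterError):
            rank_and_split(part, ids, fuzzy_order="distance")

    def test_partition_frame_roundtrip(self, rng):
        U = rng.random((12, 3))
        U /= U.sum(axis=1, keepdims=True)
        ids = [f"s{i:02d}" for i in range(12)]
        lists = rank_and_split(self.make_partition(U), ids)
        frame = partition_frame(lists)
        rebuilt = cluster_lists_from_frame(frame)
        for a, b in zip(lists, rebuilt):
            assert a.ordered_specimens == b.ordered_specimens
            assert a.unique_region == b.unique_region
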