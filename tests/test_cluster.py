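"""Dropout binarization, distances, DBSCAN and the parameter search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

from celldrop.cluster import (
    DistanceMatrix,
    NoClusterStructureError,
    binarize,
    dbscan,
    manhattan_distance,
    select_dbscan_params,
    silhouette,
    zscore_distances,
)

from conftest import make_matrix


def brute_force_dbscan(D: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Reference DBSCAN by explicit reachability expansion.

    Core iff >= min_pts points (self included) within eps; clusters grow by
    breadth-first expansion from cores in ascending index order; border
    points take the cluster of their lowest-index core neighbour; then the
    same renumbering convention (decreasing size, ties by smallest member).
    """
    n = D.shape[0]
    within = D <= eps
    core = within.sum(axis=1) >= min_pts
    labels = np.full(n, 0)
    cur = 0
    for i in range(n):
        if not core[i] or labels[i] != 0:
            continue
        cur += 1
        frontier = [i]
        labels[i] = cur
        while frontier:
            q = frontier.pop()
            for j in np.flatnonzero(within[q]):
                if core[j] and labels[j] == 0:
                    labels[j] = cur
                    frontier.append(j)
    out = np.full(n, -1)
    for i in range(n):
        if core[i]:
            out[i] = labels[i]
        else:
            for j in np.flatnonzero(within[i]):
                if core[j]:
                    out[i] = labels[j]
                    break
    # renumber by decreasing size, ties by smallest member index
    final = np.full(n, -1)
    uniq = [l for l in np.unique(out) if l != -1]
    order = sorted(uniq, key=lambda l: (-(out == l).sum(), np.flatnonzero(out == l)[0]))
    for new, old in enumerate(order, start=1):
        final[out == old] = new
    return final


def dist(values) -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(values, [f"c{i}" for i in range(values.shape[0])])


class TestBinarize:
    def test_threshold_at_zero(self):
        b = binarize(make_matrix([[0, 0.2, 5, 0]]))
        np.testing.assert_array_equal(b.values, [[0, 1, 1, 0]])

    def test_all_zero_cell(self):
        b = binarize(make_matrix([[0, 0], [1, 2]]))
        np.testing.assert_array_equal(b.values[0], [0, 0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.poisson(0.7, (10, 20)).astype(float))
        once = binarize(m)
        twice = binarize(make_matrix(once.values.astype(float)))
        np.testing.assert_array_equal(once.values, twice.values)


class TestManhattan:
    def test_worked_example(self):
        d = manhattan_distance(np.array([[1, 0, 3], [0, 2, 3]], dtype=float))
        assert d.values[0, 1] == 3

    def test_identical_cells_zero(self):
        d = manhattan_distance(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.values[0, 1] == 0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (5, 4)).astype(float)
        d = manhattan_distance(X)
        for i in range(5):
            for j in range(5):
                assert d.values[i, j] == np.abs(X[i] - X[j]).sum()

    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 3))
        D = manhattan_distance(X).values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestZscore:
    def test_three_cell_worked_example(self):
        # off-diagonal distances {2, 4, 6}: mean 4, sample sd 2 → {−1, 0, 1}
        D = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        z = zscore_distances(dist(D))
        assert z.values[0, 1] == pytest.approx(-1)
        assert z.values[0, 2] == pytest.approx(0)
        assert z.values[1, 2] == pytest.approx(1)
        assert z.zscored

    def test_monotone(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 4))
        d = manhattan_distance(X)
        z = zscore_distances(d)
        iu = np.triu_indices(8, 1)
        assert (np.argsort(d.values[iu]) == np.argsort(z.values[iu])).all()

    def test_degenerate_rejected(self):
        D = np.full((3, 3), 5.0)
        np.fill_diagonal(D, 0)
        with pytest.raises(ValueError, match="degenerate"):
            zscore_distances(dist(D))


class TestDBSCAN:
    def test_two_groups_of_three(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        a = dbscan(manhattan_distance(X), eps=1.5, min_pts=2)
        assert a.n_clusters == 2 and a.n_noise == 0
        assert len(set(a.labels[:3])) == 1 and len(set(a.labels[3:])) == 1

    def test_isolated_point_is_noise(self):
        X = np.array([[0.0], [0.5], [1.0], [50.0]])
        a = dbscan(manhattan_distance(X), eps=1.0, min_pts=3)
        assert a.labels[3] == -1

    def test_eps_below_min_distance_all_noise(self):
        X = np.array([[0.0], [5.0], [10.0]])
        a = dbscan(manhattan_distance(X), eps=1.0, min_pts=2)
        assert (a.labels == -1).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        X = rng.normal(size=(n, 2)) * rng.choice([0.3, 1.0, 3.0])
        d = manhattan_distance(X)
        eps = np.quantile(d.offdiag(), rng.uniform(0.05, 0.5))
        min_pts = int(rng.integers(2, 6))
        mine = dbscan(d, eps, min_pts).labels
        ref = brute_force_dbscan(d.values, eps, min_pts)
        np.testing.assert_array_equal(mine, ref)

    def test_invariant_under_affine_transform(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        d = manhattan_distance(X)
        z = zscore_distances(d)
        eps = np.quantile(d.offdiag(), 0.2)
        eps_z = (eps - z.zscore_mu) / z.zscore_sigma
        np.testing.assert_array_equal(
            dbscan(d, eps, 3).labels, dbscan(z, eps_z, 3).labels
        )

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 2))
        d = manhattan_distance(X)
        a = dbscan(d, 1.0, 3).labels
        b = dbscan(d, 1.0, 3).labels
        np.testing.assert_array_equal(a, b)


class TestSilhouette:
    def test_two_tight_pairs(self):
        D = manhattan_distance(np.array([[0.0], [0.0], [10.0], [10.0]]))
        assert silhouette(D, np.array([1, 1, 2, 2])) == pytest.approx(1.0)

    def test_single_cluster_sentinel(self):
        D = manhattan_distance(np.array([[0.0], [1.0], [2.0]]))
        assert silhouette(D, np.array([1, 1, 1])) == -1.0

    def test_three_point_hand_computation(self):
        # d(1,2)=1, d(1,3)=4, d(2,3)=4; labels (1,1,2)
        # point1: a=1, b=4 → 0.75; point2: a=1, b=4 → 0.75;
        # point3: singleton cluster → 0; mean = 0.5
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        s = silhouette(dist(D), np.array([1, 1, 2]))
        assert s == pytest.approx((0.75 + 0.75 + 0.0) / 3)

    def test_noise_excluded(self):
        D = manhattan_distance(np.array([[0.0], [0.1], [10.0], [10.1], [500.0]]))
        s_with = silhouette(D, np.array([1, 1, 2, 2, -1]))
        s_without = silhouette(
            manhattan_distance(np.array([[0.0], [0.1], [10.0], [10.1]])),
            np.array([1, 1, 2, 2]),
        )
        assert s_with == pytest.approx(s_without)

    def test_matches_sklearn_without_noise(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(5, 1, (12, 3))])
        labels = np.array([1] * 10 + [2] * 12)
        d = manhattan_distance(X)
        ours = silhouette(d, labels)
        ref = silhouette_score(d.values, labels, metric="precomputed")
        assert ours == pytest.approx(ref, rel=1e-12)


class TestParamSearch:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (20, 2)), rng.normal(8, 0.5, (20, 2))])
        dz = zscore_distances(manhattan_distance(X))
        p = select_dbscan_params(dz, eps_step=0.01)
        assert p.n_clusters == 2
        assert p.silhouette > 0.9
        # exhaustive check: no examined sweep can beat the returned pair
        a = dbscan(dz, p.eps, p.min_pts)
        assert silhouette(dz, a.labels) == pytest.approx(p.silhouette)

    def test_two_point_pairs_perfect_silhouette(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        dz = zscore_distances(manhattan_distance(X))
        p = select_dbscan_params(dz, init_min_pts=4, eps_step=0.01)
        assert p.silhouette == pytest.approx(1.0)
        assert p.n_clusters == 2 and p.n_noise == 0

    def test_identical_points_error(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError, match="degenerate"):
            zscore_distances(manhattan_distance(X))

    def test_structureless_data_raises(self):
        # an equally spaced chain has no density structure: any eps either
        # joins all points into one cluster or leaves them all noise
        X = np.arange(12, dtype=float).reshape(-1, 1)
        dz = zscore_distances(manhattan_distance(X))
        with pytest.raises(NoClusterStructureError):
            select_dbscan_params(dz, eps_step=0.05, min_valid_frac=0.99)
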