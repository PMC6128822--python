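from itertools import product

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

import cuetopo as ct
from cuetopo.synthetic import sample_hotspots


def brute_force_two_partition_wcss(X):
    """Global optimum over all 2-partitions (independent oracle, n <= 12)."""
    n = len(X)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        wcss = 0.0
        for lab in (0, 1):
            members = X[labels == lab]
            if len(members) == 0:
                break
            wcss += ((members - members.mean(axis=0)) ** 2).sum()
        else:
            best = min(best, wcss)
    return best


class TestKmeansppSeed:
    def test_k_equals_n_returns_permutation(self):
        X = np.arange(15, dtype=float).reshape(5, 3)
        rng = np.random.default_rng(0)
        seeds = ct.kmeanspp_seed(X, 5, rng)
        assert sorted(map(tuple, seeds)) == sorted(map(tuple, X))

    def test_k_one_is_uniform_draw(self):
        X = np.arange(9, dtype=float).reshape(3, 3)
        seeds = ct.kmeanspp_seed(X, 1, np.random.default_rng(1))
        assert any((seeds[0] == x).all() for x in X)

    def test_two_far_groups_get_one_seed_each(self):
        """D^2 weighting near-certainly splits two far tight groups."""
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.5, (20, 3)), rng.normal(200, 0.5, (20, 3))])
        hits = 0
        for _ in range(1000):
            seeds = ct.kmeanspp_seed(X, 2, rng)
            sides = {s[0] > 100 for s in seeds}
            hits += len(sides) == 2
        assert hits >= 990

    def test_k_exceeding_distinct_points_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            ct.kmeanspp_seed(X, 2, np.random.default_rng(0))


class TestKmeansFit:
    def test_k_equals_n_gives_zero_wcss(self):
        X = np.random.default_rng(3).normal(size=(6, 3)) * 10
        sol = ct.kmeans_fit(X, 6, n_restarts=20, rng=0)
        assert sol.wcss == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3)) * 20
        sol = ct.kmeans_fit(X, 2, n_restarts=50, rng=seed)
        assert sol.wcss == pytest.approx(brute_force_two_partition_wcss(X), rel=1e-9)

    def test_matches_sklearn_cross_check(self):
        """Independent route: scikit-learn's k-means finds the same optimum."""
        from sklearn.cluster import KMeans
        X = sample_hotspots(ct.DEFAULT_MIXTURE, 120, seed=5).coords
        ours = ct.kmeans_fit(X, 3, n_restarts=100, rng=0)
        ref = KMeans(n_clusters=3, n_init=50, random_state=0).fit(X)
        assert ours.wcss <= ref.inertia_ * (1 + 1e-9)
        ours_sorted = np.array(sorted(map(tuple, ours.centroids)))
        ref_sorted = np.array(sorted(map(tuple, ref.cluster_centers_)))
        np.testing.assert_allclose(ours_sorted, ref_sorted, atol=1e-6)

    def test_planted_centroid_recovery(self, mixture):
        sol = ct.kmeans_fit(sample_hotspots(mixture, 261, seed=1).coords,
                            3, n_restarts=100, rng=1)
        D = cdist(sol.centroids, mixture.centroids)
        # each recovered centroid within 6 mm of a distinct planted one
        assignment = D.argmin(axis=1)
        assert sorted(assignment) == [0, 1, 2]
        assert np.all(D.min(axis=1) < 6.0)

    def test_assignments_are_nearest_centroid(self):
        X = sample_hotspots(ct.DEFAULT_MIXTURE, 60, seed=2).coords
        sol = ct.kmeans_fit(X, 3, n_restarts=20, rng=2)
        d = cdist(X, sol.centroids)
        np.testing.assert_array_equal(sol.assignments, d.argmin(axis=1))

    def test_more_restarts_never_worse(self):
        X = sample_hotspots(ct.DEFAULT_MIXTURE, 80, seed=3).coords
        one = ct.kmeans_fit(X, 4, n_restarts=1, rng=7)
        many = ct.kmeans_fit(X, 4, n_restarts=100, rng=7)
        assert many.wcss <= one.wcss + 1e-12

    def test_invariant_to_point_order_and_translation(self):
        X = sample_hotspots(ct.DEFAULT_MIXTURE, 50, seed=4).coords
        sol = ct.kmeans_fit(X, 3, n_restarts=50, rng=11)
        perm = np.random.default_rng(0).permutation(len(X))
        sol_perm = ct.kmeans_fit(X[perm], 3, n_restarts=50, rng=11)
        assert sol_perm.wcss == pytest.approx(sol.wcss, rel=1e-9)
        shift = np.array([100.0, -50.0, 25.0])
        sol_shift = ct.kmeans_fit(X + shift, 3, n_restarts=50, rng=11)
        assert sol_shift.wcss == pytest.approx(sol.wcss, rel=1e-9)
        np.testing.assert_allclose(np.sort(sol_shift.centroids, axis=0),
                                   np.sort(sol.centroids, axis=0) + shift, atol=1e-6)

    def test_fewer_distinct_points_than_k_rejected(self):
        with pytest.raises(ValueError):
            ct.kmeans_fit(np.zeros((5, 3)), 2, n_restarts=1, rng=0)


class TestSilhouettes:
    def test_hand_computed_six_points(self):
        """Direct-formula oracle on 6 hand-placed 1D-ish points."""
        X = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                      [10.0, 0, 0], [11.0, 0, 0], [12.0, 0, 0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        s, mean = ct.silhouette_scores(X, labels)
        # point 0: a = (1+2)/2 = 1.5 ; b = (10+11+12)/3 = 11 ; s = 9.5/11
        assert s[0] == pytest.approx((11 - 1.5) / 11)
        # point 2: a = (2+1)/2 = 1.5 ; b = (8+9+10)/3 = 9 ; s = 7.5/9
        assert s[2] == pytest.approx((9 - 1.5) / 9)
        np.testing.assert_allclose(s[:3][::-1], s[3:])  # mirror symmetry

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import silhouette_samples
        X = sample_hotspots(ct.DEFAULT_MIXTURE, 150, seed=6).coords
        labels = ct.kmeans_fit(X, 3, n_restarts=20, rng=0).assignments
        ours, _ = ct.silhouette_scores(X, labels)
        np.testing.assert_allclose(ours, silhouette_samples(X, labels), atol=1e-10)

    def test_two_tight_far_groups_near_one(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(100, 1, (30, 3))])
        labels = np.array([0] * 30 + [1] * 30)
        _, mean = ct.silhouette_scores(X, labels)
        assert mean > 0.95

    def test_identical_points_score_zero(self):
        X = np.zeros((6, 3))
        labels = np.array([0, 0, 0, 1, 1, 1])
        s, mean = ct.silhouette_scores(X, labels)
        assert np.all(s == 0.0) and mean == 0.0

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0, 0, 0], [1.0, 0, 0], [50.0, 0, 0]])
        s, _ = ct.silhouette_scores(X, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_values_bounded(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, 40)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        s, _ = ct.silhouette_scores(X, labels)
        assert np.all(s >= -1) and np.all(s <= 1)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ct.silhouette_scores(np.zeros((4, 3)), np.zeros(4, dtype=int))


class TestSelectK:
    def test_three_component_cohort_selects_three(self, mixture):
        hs = sample_hotspots(mixture, 261, seed=10)
        sol, diag = ct.select_k(hs.coords, 2, 10, n_restarts=50, seed=10)
        assert sol.k == 3
        assert not diag["weak_structure"].iloc[0]

    def test_two_component_cohort_selects_two(self):
        spec = ct.MixtureSpec(centroids=[[0, 0, 0], [60, 0, 0]],
                              weights=[0.5, 0.5], dispersion_mm=8.0)
        hs = sample_hotspots(spec, 120, seed=11)
        sol, _ = ct.select_k(hs.coords, 2, 8, n_restarts=30, seed=11)
        assert sol.k == 2

    def test_single_cloud_flagged_weak_with_smallest_k_tie_rule(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 10, size=(100, 3))
        sol, diag = ct.select_k(X, 2, 6, n_restarts=20, seed=12)
        assert diag["weak_structure"].iloc[0] or sol.mean_silhouette < 0.45
        ties = diag[diag["mean_silhouette"] == diag["mean_silhouette"].max()]
        assert sol.k == int(ties["k"].min())

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty k range"):
            ct.SilhouetteKSelector(k_min=5, k_max=2).fit(np.zeros((10, 3)))

    def test_selector_estimator_attributes(self, mixture):
        sel = ct.SilhouetteKSelector(k_min=2, k_max=4, n_restarts=20, random_state=0)
        X = sample_hotspots(mixture, 90, seed=13).coords
        sel.fit(X)
        assert sel.n_clusters_ == 3
        assert sel.cluster_centers_.shape == (3, 3)
        assert len(sel.labels_) == 90
        params = sel.get_params()
        assert params["n_restarts"] == 20


class TestCrossTab:
    def _hotspot_set(self, groups, coords=None):
        n = len(groups)
        coords = coords if coords is not None else np.zeros((n, 3))
        points = [ct.Hotspot(subject_id=f"s{i}", group=g, x_mm=float(coords[i][0]),
                             y_mm=float(coords[i][1]), z_mm=float(coords[i][2]),
                             peak_t=1.0, cluster_size_voxels=1, cluster_rank=1,
                             sex="M" if i % 2 else "F")
                  for i, g in enumerate(groups)]
        return ct.HotspotSet(points=points, mode="full_complement")

    def _solution(self, assignments):
        assignments = np.asarray(assignments)
        k = assignments.max() + 1
        return ct.KMeansSolution(k=k, centroids=np.zeros((k, 3)),
                                 assignments=assignments, wcss=0.0,
                                 silhouettes=np.zeros(len(assignments)),
                                 mean_silhouette=0.0, n_restarts=1, seed=0)

    def test_identical_distribution_gives_zero_chi2(self):
        groups = ["cocaine"] * 10 + ["alcohol"] * 10
        assignments = ([0] * 5 + [1] * 5) * 2
        res = ct.cross_tab(self._hotspot_set(groups), self._solution(assignments))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computed_expected_counts(self):
        """2x2 table [[10,20],[20,10]]: chi2 = 60*(10*10-20*20)^2/(30^4) = 6.667."""
        groups = ["cocaine"] * 30 + ["alcohol"] * 30
        assignments = [0] * 10 + [1] * 20 + [0] * 20 + [1] * 10
        res = ct.cross_tab(self._hotspot_set(groups), self._solution(assignments))
        assert res.chi2 == pytest.approx(20 / 3, rel=1e-9)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(20 / 3, 1))

    def test_null_p_values_uniform_over_replicates(self):
        """Group-independent assignment => p ~ Uniform(0,1) (KS check)."""
        rng = np.random.default_rng(20)
        pvals = []
        for _ in range(300):
            groups = list(rng.choice(["cocaine", "alcohol", "nicotine"], 90))
            assignments = rng.integers(0, 3, 90)
            if len(np.unique(assignments)) < 2 or len(set(groups)) < 2:
                continue
            res = ct.cross_tab(self._hotspot_set(groups), self._solution(assignments))
            pvals.append(res.p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_low_expected_count_warning(self):
        groups = ["cocaine"] * 4 + ["alcohol"] * 4
        assignments = [0, 0, 1, 1] * 2
        res = ct.cross_tab(self._hotspot_set(groups), self._solution(assignments))
        assert res.low_expected_warning

    def test_sex_factor(self):
        groups = ["cocaine"] * 20
        res = ct.cross_tab(self._hotspot_set(groups),
                           self._solution([0, 1] * 10), factor="sex")
        assert res.df == 1

    def test_degenerate_table_rejected(self):
        groups = ["cocaine"] * 10
        with pytest.raises(ValueError, match="degenerate"):
            ct.cross_tab(self._hotspot_set(groups), self._solution([0, 1] * 5))
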