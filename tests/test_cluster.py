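import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

import posespace as ps
from posespace.cluster import EmptyPoseSpaceError, PoseSpaceError
from _oracles import filter_recount, welch_z_oracle

coords3 = st.lists(
    st.tuples(*[st.floats(-10, 10, allow_nan=False)] * 3),
    min_size=4, max_size=4,
)


def _features(cart, compound_ids=None):
    """Wrap a raw (N, 3m) Cartesian array as a FeatureMatrix."""
    cart = np.asarray(cart, dtype=float)
    n, m3 = cart.shape
    m = m3 // 3
    sph = np.vstack([
        ps.to_spherical(row.reshape(m, 3)).ravel() for row in cart
    ])
    ids = compound_ids if compound_ids is not None else ["X"] * n
    keys = [(cid, "s", i + 1) for i, cid in enumerate(ids)]
    return ps.FeatureMatrix(keys=keys, cartesian=cart, spherical=sph,
                            core_labels=[f"A{j}" for j in range(m)])


class TestPoseRmsd:
    def test_identical_sets_have_zero_rmsd(self):
        a = np.arange(12.0).reshape(4, 3)
        assert ps.pose_rmsd(a, a) == 0.0

    def test_single_displaced_atom_closed_form(self):
        a = np.zeros((4, 3))
        b = a.copy()
        b[0, 2] = 2.0  # one atom displaced by 2 Å, m=4 → 2/√4 = 1
        assert ps.pose_rmsd(a, b) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(PoseSpaceError):
            ps.pose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    @given(coords3, coords3, coords3)
    def test_metric_axioms_on_random_triples(self, a, b, c):
        a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
        dab = ps.pose_rmsd(a, b)
        assert dab >= 0
        assert dab == pytest.approx(ps.pose_rmsd(b, a))
        assert ps.pose_rmsd(a, a) == 0.0
        assert dab <= ps.pose_rmsd(a, c) + ps.pose_rmsd(c, b) + 1e-9


@pytest.fixture(scope="module")
def planted():
    """Three modes separated by >= 10× the jitter σ."""
    rng = np.random.default_rng(3)
    centers = np.array([[0.0, 0, 0], [8, 0, 0], [0, 8, 0]])
    sigma = 0.2
    rows, truth = [], []
    for i, c in enumerate(centers):
        base = np.tile(c, 4)  # m = 4 atoms around the center
        rows.append(base + rng.normal(0, sigma, (40, 12)))
        truth.extend([i] * 40)
    return np.vstack(rows), np.array(truth)


class TestClusterPoses:
    def test_planted_modes_recovered_exactly(self, planted):
        X, truth = planted
        clustering = ps.cluster_poses(_features(X), n_clusters=3)
        assert adjusted_rand_score(truth, clustering.labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        X = np.random.default_rng(0).normal(size=(12, 6))
        clustering = ps.cluster_poses(_features(X), n_clusters=12)
        assert len(set(clustering.labels)) == 12

    def test_k_one_gives_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(12, 6))
        clustering = ps.cluster_poses(_features(X), n_clusters=1)
        assert set(clustering.labels) == {1}

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(PoseSpaceError):
            ps.cluster_poses(_features(np.zeros((3, 6))), n_clusters=4)

    def test_partition_invariant_to_row_order(self, planted):
        X, _ = planted
        perm = np.random.default_rng(1).permutation(len(X))
        base = ps.cluster_poses(_features(X), n_clusters=3).labels
        shuffled = ps.cluster_poses(_features(X[perm]), n_clusters=3).labels
        assert adjusted_rand_score(base[perm], shuffled) == 1.0

    def test_estimator_api_round_trips_params(self):
        est = ps.PoseClusterer(n_clusters=5, linkage="average", min_count=3)
        assert ps.PoseClusterer(**est.get_params()).get_params() == \
            est.get_params()


class TestFilterClusters:
    def _clustering(self, labels):
        labels = np.asarray(labels)
        return ps.PoseClustering(
            n_clusters=int(labels.max()), labels=labels,
            linkage_method="ward",
            keys=[("", "", i + 1) for i in range(len(labels))])

    def test_hand_enumerated_example(self):
        """A=(12,3,0), B=(0,10,5), C=(2,11,0) over 3 clusters: clusters 1
        and 2 retained (12 > 10, 11 > 10), cluster 3 dropped (max 5 <= 10);
        38 of 43 poses survive."""
        labels, compounds = [], []
        for cid, counts in (("A", (12, 3, 0)), ("B", (0, 10, 5)),
                            ("C", (2, 11, 0))):
            for cluster, n in enumerate(counts, start=1):
                labels += [cluster] * n
                compounds += [cid] * n
        filtered = ps.filter_clusters(self._clustering(labels), compounds,
                                      min_count=10)
        assert filtered.retained.tolist() == [True, True, False]
        assert filtered.retained_pose_count == 38
        assert len(labels) == 43

    def test_min_count_zero_retains_every_nonempty_cluster(self):
        filtered = ps.filter_clusters(self._clustering([1, 2, 3, 3]),
                                      ["A", "A", "B", "B"], min_count=0)
        assert filtered.retained.all()

    def test_all_below_threshold_empties_pose_space(self):
        filtered = ps.filter_clusters(self._clustering([1, 1, 2]),
                                      ["A", "B", "A"], min_count=10)
        assert filtered.n_retained_clusters == 0
        with pytest.raises(EmptyPoseSpaceError):
            ps.centroid_distances(filtered, np.zeros((3, 3)))

    def test_renumbering_preserves_original_cluster_order(self):
        labels = [1, 2, 3, 4] * 12
        compounds = ["A"] * 48
        filtered = ps.filter_clusters(self._clustering(labels), compounds,
                                      min_count=11)
        # every cluster has 12 > 11 poses of A → all retained, ids stable
        assert filtered.filtered_labels.tolist() == labels
        filtered = ps.filter_clusters(self._clustering(labels), compounds,
                                      min_count=12)
        assert filtered.n_retained_clusters == 0

    @pytest.mark.parametrize("trial", range(100))
    def test_agrees_with_bruteforce_recount(self, trial):
        rng = np.random.default_rng(trial)
        n_clusters = rng.integers(1, 8)
        n_compounds = rng.integers(1, 6)
        n_poses = rng.integers(n_clusters, 51)
        min_count = int(rng.integers(0, 12))
        labels = rng.integers(1, n_clusters + 1, n_poses)
        labels[:n_clusters] = np.arange(1, n_clusters + 1)  # no empty ids
        compounds = rng.choice([f"c{i}" for i in range(n_compounds)], n_poses)
        filtered = ps.filter_clusters(self._clustering(labels), compounds,
                                      min_count=min_count)
        expected = filter_recount(labels, compounds, min_count)
        assert {k + 1 for k in np.flatnonzero(filtered.retained)} == expected
        assert filtered.retained_pose_count == sum(
            lab in expected for lab in labels)


class TestPcaReduce:
    def test_axis_aligned_gaussian_recovers_axes(self):
        """Uncorrelated axis-aligned cloud: components align with the input
        axes (up to sign) and variances come out sorted."""
        rng = np.random.default_rng(0)
        X = rng.normal(0, [5.0, 2.0, 0.5], size=(4000, 3))
        res = ps.pca_reduce(np.abs(X) + 1.0, encoding="radians")
        # use radians encoding so columns map 1:1 onto input axes
        directions = np.abs(res.loadings)
        assert np.allclose(directions, np.eye(3), atol=0.05)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_full_rank_reconstruction(self, small_run):
        ensemble, _ = small_run
        feats = ps.extract_features(ensemble)
        res = ps.pca_reduce(feats)
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, res.encoded, atol=1e-9)

    def test_component_scores_uncorrelated(self, small_run):
        ensemble, _ = small_run
        res = ps.pca_reduce(ps.extract_features(ensemble))
        nontrivial = res.scores[:, res.explained_variance_ratio > 1e-12]
        cov = np.cov(nontrivial, rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)),
                                   0.0, atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(PoseSpaceError, match="degenerate"):
            ps.pca_reduce(np.ones((10, 6)), encoding="radians")

    def test_sincos_encoding_has_no_wraparound_discontinuity(self):
        # two angles straddling ±π are distant in radians but close encoded
        sph = np.array([[1.0, np.pi / 2, np.pi - 0.01],
                        [1.0, np.pi / 2, -np.pi + 0.01]])
        enc, _ = ps.encode_spherical(sph)
        assert np.linalg.norm(enc[0] - enc[1]) < 0.05


class TestCentroidDistances:
    def _filtered_singletons(self, n):
        labels = np.arange(1, n + 1)
        clustering = ps.PoseClustering(
            n_clusters=n, labels=labels, linkage_method="ward",
            keys=[("", "", i + 1) for i in range(n)])
        return ps.filter_clusters(clustering, ["A"] * n, min_count=0)

    def test_two_singletons_euclidean_distance(self):
        clustering = self._filtered_singletons(2)
        scores = np.array([[0.0, 0, 0], [3, 4, 0]])
        geo = ps.centroid_distances(clustering, scores)
        assert geo.distances[0, 1] == pytest.approx(5.0)

    def test_matrix_symmetric_zero_diagonal(self, paper_run):
        *_, result = paper_run
        D = result.geometry.distances
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert np.all(D >= 0)

    def test_planted_mode_geometry_ordering(self, paper_run):
        """Centroid distances reproduce the planted geometry: their ordering
        (and, within a few %, their values) matches the pairwise distances
        between the ground-truth mode means in the encoded feature space —
        an oracle that never touches clustering or PCA.  Four mode means
        span at most three dimensions, so three components lose nothing."""
        spec, ensemble, truth, result = paper_run
        cl = result.clustering
        planted = truth.mode_array(result.features.keys)
        encoded, _ = ps.encode_spherical(result.features.spherical)
        mode_ids = sorted({m.mode_id for m in spec.modes})
        means = np.array([encoded[planted == m].mean(axis=0)
                          for m in mode_ids])
        oracle = np.linalg.norm(means[:, None] - means[None], axis=-1)
        # align retained-cluster order with planted-mode order
        perm = []
        for k in range(1, cl.n_retained_clusters + 1):
            modes, counts = np.unique(planted[cl.filtered_labels == k],
                                      return_counts=True)
            perm.append(mode_ids.index(modes[np.argmax(counts)]))
        oracle = oracle[np.ix_(perm, perm)]
        iu = np.triu_indices(len(perm), 1)
        assert (np.argsort(oracle[iu])
                == np.argsort(result.geometry.distances[iu])).all()
        np.testing.assert_allclose(result.geometry.distances[iu],
                                   oracle[iu], rtol=0.05)

    def test_too_few_components_rejected(self):
        clustering = self._filtered_singletons(2)
        with pytest.raises(PoseSpaceError):
            ps.centroid_distances(clustering, np.zeros((2, 2)),
                                  n_components=3)


class TestSubsetScoreTest:
    def _two_cluster_partition(self, scores_a, scores_b):
        n_a, n_b = len(scores_a), len(scores_b)
        labels = np.array([1] * n_a + [2] * n_b)
        clustering = ps.PoseClustering(
            n_clusters=2, labels=labels, linkage_method="ward",
            keys=[("", "", i + 1) for i in range(n_a + n_b)])
        clustering = ps.filter_clusters(clustering, ["A"] * (n_a + n_b),
                                        min_count=0)
        scores = np.concatenate([scores_a, scores_b])
        return scores, clustering

    def test_identical_distributions_statistic_zero_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        scores, clustering = self._two_cluster_partition(vals, vals)
        res = ps.subset_score_test(scores, clustering, {1: 0, 2: 1})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_gaussian_shift_matches_z_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(50, 1, 500)
        b = rng.normal(60, 1, 500)
        scores, clustering = self._two_cluster_partition(a, b)
        res = ps.subset_score_test(scores, clustering, {1: 0, 2: 1})
        z, _ = welch_z_oracle(a, b)
        assert res.statistic == pytest.approx(z)
        assert res.p_value < 1e-10

    def test_swapping_subsets_negates_statistic(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
        scores, clustering = self._two_cluster_partition(a, b)
        fwd = ps.subset_score_test(scores, clustering, {1: 0, 2: 1})
        rev = ps.subset_score_test(scores, clustering, {1: 1, 2: 0})
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_permutation_variant_agrees_on_strong_effect(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 100), rng.normal(3, 1, 100)
        scores, clustering = self._two_cluster_partition(a, b)
        res = ps.subset_score_test(scores, clustering, {1: 0, 2: 1},
                                   method="permutation", seed=0)
        assert res.p_value < 0.01

    def test_incomplete_partition_rejected(self):
        rng = np.random.default_rng(2)
        scores, clustering = self._two_cluster_partition(
            rng.normal(size=10), rng.normal(size=10))
        with pytest.raises(PoseSpaceError, match="partition"):
            ps.subset_score_test(scores, clustering, {1: 0})
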