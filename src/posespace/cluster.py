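"""Pose-space clustering and geometry.

Poses are clustered by the RMSD of their core atoms in the shared anchored
frame (no re-superposition), using agglomerative clustering pooled across all
compounds and cut at a fixed number of clusters K.  Clusters in which no
single compound places strictly more than ``min_count`` poses are discarded,
together with their poses.  Cluster dissimilarity is measured between cluster
centroids in the first three principal components of the (encoded) spherical
coordinates; angular coordinates are sin/cos-encoded by default so that PCA
never sees the wrap-around discontinuity at ±π.

Because RMSD over fixed-order coordinate sets is the Euclidean distance of
the flattened coordinates divided by √m, Ward linkage on the scaled
coordinates is an exact RMSD hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .frame import FeatureMatrix


class PoseSpaceError(ValueError):
    pass


class EmptyPoseSpaceError(PoseSpaceError):
    """No retained clusters survive the population filter."""


def pose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two same-order core-atom coordinate sets (Å).

    sqrt(mean over atoms of squared Euclidean deviation); no superposition —
    both sets are assumed already expressed in the shared anchored frame.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise PoseSpaceError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class PoseClustering:
    """Cluster label per pose plus the population-filter state.

    ``labels`` are 1..K over all poses.  After :func:`filter_clusters`,
    ``retained`` flags each original cluster, ``filtered_labels`` renumbers
    retained clusters 1..K′ (preserving original order) with 0 marking poses
    of discarded clusters, and ``retained_pose_count`` counts surviving poses.
    """

    n_clusters: int
    labels: np.ndarray
    linkage_method: str
    keys: list[tuple[str, str, int]]
    retained: np.ndarray | None = None       # (K,) bool, index = cluster-1
    filtered_labels: np.ndarray | None = None
    min_count: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.n_clusters:
            raise PoseSpaceError("labels outside 1..K")
        if len(self.keys) != len(self.labels):
            raise PoseSpaceError("one key per pose required")

    @property
    def is_filtered(self) -> bool:
        return self.retained is not None

    @property
    def n_retained_clusters(self) -> int:
        self._require_filtered()
        return int(self.retained.sum())

    @property
    def retained_pose_count(self) -> int:
        self._require_filtered()
        return int((self.filtered_labels > 0).sum())

    @property
    def retained_pose_mask(self) -> np.ndarray:
        self._require_filtered()
        return self.filtered_labels > 0

    def _require_filtered(self) -> None:
        if not self.is_filtered:
            raise PoseSpaceError("clustering has not been filtered yet")


class PoseClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative RMSD clustering of poses with the population filter.

    Parameters
    ----------
    n_clusters:
        Number of clusters K the hierarchy is cut at (80 and 40 are the
        values used for the two binding sites in the reference workflow).
    linkage:
        "ward" (default; exact, since RMSD is a scaled Euclidean metric on
        fixed-order coordinates) or "average".
    min_count:
        A cluster is retained iff some compound has strictly more than this
        many poses in it.  ``None`` disables filtering at fit time.

    Attributes (after ``fit``)
    ----------
    labels_ : (N,) int, cluster label 1..K per pose.
    clustering_ : :class:`PoseClustering` (filtered when ``min_count`` is set
        and compound ids were available).
    """

    def __init__(self, n_clusters: int = 80, linkage: str = "ward",
                 min_count: int | None = 10):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.min_count = min_count

    def fit(self, X, y=None, compound_ids=None, keys=None):
        """Cluster poses.

        ``X`` is either a :class:`FeatureMatrix` or an (N, 3m) array of
        Cartesian in-frame coordinates.  ``compound_ids`` (or a
        FeatureMatrix's own ids) enable the population filter.
        """
        if isinstance(X, FeatureMatrix):
            compound_ids = X.compound_ids if compound_ids is None else compound_ids
            keys = X.keys if keys is None else keys
            X = X.cartesian
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.n_clusters < 1:
            raise PoseSpaceError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.n_clusters > n:
            raise PoseSpaceError(f"n_clusters={self.n_clusters} exceeds {n} poses")
        if X.ndim != 2 or X.shape[1] % 3:
            raise PoseSpaceError("X must be (N, 3m) flattened coordinates")
        if not np.all(np.isfinite(X)):
            raise PoseSpaceError("features contain non-finite values")
        if self.linkage not in ("ward", "average"):
            raise PoseSpaceError(f"unsupported linkage {self.linkage!r}")
        m = X.shape[1] // 3
        scaled = X / np.sqrt(m)  # Euclidean on scaled rows == pose RMSD
        if self.linkage == "ward":
            Z = scipy_linkage(scaled, method="ward")
        else:
            Z = scipy_linkage(pdist(scaled), method="average")
        labels = fcluster(Z, t=self.n_clusters, criterion="maxclust")
        labels = _canonical_labels(labels)
        if keys is None:
            keys = [("", "", i + 1) for i in range(n)]
        self.clustering_ = PoseClustering(
            n_clusters=self.n_clusters, labels=labels,
            linkage_method=self.linkage, keys=list(keys),
        )
        if self.min_count is not None and compound_ids is not None:
            self.clustering_ = filter_clusters(
                self.clustering_, compound_ids, self.min_count
            )
        self.labels_ = self.clustering_.labels
        return self

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, y, **kw).labels_


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..K by first appearance in row order, so the
    labeling is independent of scipy's internal cluster numbering."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_poses(features: FeatureMatrix, n_clusters: int,
                  linkage: str = "ward") -> PoseClustering:
    """Pooled agglomerative RMSD clustering cut at ``n_clusters`` (unfiltered)."""
    est = PoseClusterer(n_clusters=n_clusters, linkage=linkage, min_count=None)
    est.fit(features)
    return est.clustering_


def filter_clusters(clustering: PoseClustering, compound_ids,
                    min_count: int = 10) -> PoseClustering:
    """Apply the per-compound population filter.

    A cluster is retained iff at least one compound has STRICTLY more than
    ``min_count`` poses in it; poses of discarded clusters are excluded from
    all downstream stages.  Retained clusters are renumbered 1..K′ in their
    original order.
    """
    compound_ids = np.asarray(compound_ids)
    if len(compound_ids) != len(clustering.labels):
        raise PoseSpaceError("one compound id per pose required")
    K = clustering.n_clusters
    retained = np.zeros(K, dtype=bool)
    for k in range(1, K + 1):
        members = compound_ids[clustering.labels == k]
        if members.size:
            _, counts = np.unique(members, return_counts=True)
            retained[k - 1] = counts.max() > min_count
    new_id = np.zeros(K + 1, dtype=int)  # old label -> new label, 0 = dropped
    new_id[1:][retained] = np.arange(1, int(retained.sum()) + 1)
    filtered_labels = new_id[clustering.labels]
    return replace(clustering, retained=retained,
                   filtered_labels=filtered_labels, min_count=min_count)


def encode_spherical(spherical: np.ndarray, encoding: str = "sincos"
                     ) -> tuple[np.ndarray, list[str]]:
    """Encode (r, θ, φ) triplets for PCA.

    ``sincos`` (default): per core atom ``[r/σ_r, sinθ, cosθ, sinφ, cosφ]``
    with each radius column scaled to unit variance, removing the ±π
    wrap-around discontinuity.  ``radians``: raw (r, θ, φ) columns.
    """
    S = np.asarray(spherical, dtype=float)
    if S.ndim != 2 or S.shape[1] % 3:
        raise PoseSpaceError("spherical matrix must be (N, 3m)")
    m = S.shape[1] // 3
    r = S[:, 0::3]
    theta = S[:, 1::3]
    phi = S[:, 2::3]
    if encoding == "radians":
        labels = [f"{pre}{j}" for j in range(m) for pre in ("r", "theta", "phi")]
        return S.copy(), labels
    if encoding != "sincos":
        raise PoseSpaceError(f"unknown encoding {encoding!r}")
    sd = r.std(axis=0, ddof=0)
    r_std = np.where(sd > 0, r / np.where(sd > 0, sd, 1.0), r)
    cols, labels = [], []
    for j in range(m):
        cols.extend([r_std[:, j], np.sin(theta[:, j]), np.cos(theta[:, j]),
                     np.sin(phi[:, j]), np.cos(phi[:, j])])
        labels.extend([f"r{j}", f"sin_theta{j}", f"cos_theta{j}",
                       f"sin_phi{j}", f"cos_phi{j}"])
    return np.column_stack(cols), labels


@dataclass
class PCAResult:
    """Mean-centered PCA of the encoded spherical coordinates."""

    scores: np.ndarray        # (N, n_comp)
    loadings: np.ndarray      # (d, n_comp), orthonormal columns
    mean: np.ndarray          # (d,)
    explained_variance_ratio: np.ndarray
    encoding: str
    encoded: np.ndarray       # (N, d) matrix the PCA consumed
    column_labels: list[str] = field(default_factory=list)


def pca_reduce(features: FeatureMatrix | np.ndarray,
               encoding: str = "sincos",
               n_components: int | None = None) -> PCAResult:
    """PCA of the (encoded) spherical coordinates.

    Adjacent core atoms have strongly cross-correlated coordinates; PCA
    decorrelates them so centroid distances in the leading components are
    meaningful.  Deterministic: full SVD with the sign of each component
    fixed so its largest-magnitude loading is positive.
    """
    sph = features.spherical if isinstance(features, FeatureMatrix) else np.asarray(features)
    if sph.shape[0] < 2:
        raise PoseSpaceError("PCA needs at least 2 poses")
    X, labels = encode_spherical(sph, encoding)
    if np.allclose(X.var(axis=0), 0.0, atol=1e-15):
        raise PoseSpaceError(
            "degenerate ensemble: encoded coordinates have zero variance"
        )
    max_rank = min(X.shape)
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # (d, k)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return PCAResult(
        scores=scores * flip, loadings=loadings * flip, mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        encoding=encoding, encoded=X, column_labels=labels,
    )


@dataclass
class ClusterGeometry:
    """Retained-cluster centroids in leading PC space and their distances."""

    centroids: np.ndarray   # (K', n_components)
    distances: np.ndarray   # (K', K') symmetric, zero diagonal
    n_components: int

    def __post_init__(self) -> None:
        if not np.allclose(self.distances, self.distances.T):
            raise PoseSpaceError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.distances), 0.0):
            raise PoseSpaceError("distance matrix diagonal not zero")


def centroid_distances(clustering: PoseClustering, pc_scores: np.ndarray,
                       n_components: int = 3) -> ClusterGeometry:
    """Euclidean distances between retained-cluster centroids in the first
    ``n_components`` principal components."""
    clustering._require_filtered()
    pc_scores = np.asarray(pc_scores, dtype=float)
    if pc_scores.shape[1] < n_components:
        raise PoseSpaceError(
            f"only {pc_scores.shape[1]} components available, need {n_components}"
        )
    if pc_scores.shape[0] != len(clustering.labels):
        raise PoseSpaceError("one score row per pose required")
    kprime = clustering.n_retained_clusters
    if kprime == 0:
        raise EmptyPoseSpaceError("no retained clusters (empty pose space)")
    centroids = np.empty((kprime, n_components))
    for k in range(1, kprime + 1):
        members = clustering.filtered_labels == k
        centroids[k - 1] = pc_scores[members, :n_components].mean(axis=0)
    dist = squareform(pdist(centroids))
    return ClusterGeometry(centroids=centroids, distances=dist,
                           n_components=n_components)


@dataclass
class SubsetScoreTest:
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    method: str


def subset_score_test(chemscores: np.ndarray, clustering: PoseClustering,
                      partition: dict[int, int], method: str = "welch",
                      n_permutations: int = 10_000,
                      seed: int | None = 0) -> SubsetScoreTest:
    """Two-sided test of mean per-pose chemscore between two cluster subsets.

    ``partition`` maps every retained cluster id (1..K′) to subset 0 or 1.
    Default is Welch's two-sample t-test; ``method="permutation"`` runs a
    seeded permutation test on the mean difference instead.
    """
    clustering._require_filtered()
    chemscores = np.asarray(chemscores, dtype=float)
    if chemscores.shape[0] != len(clustering.labels):
        raise PoseSpaceError("one chemscore per pose required")
    kprime = clustering.n_retained_clusters
    ids = set(partition)
    if ids != set(range(1, kprime + 1)):
        raise PoseSpaceError(
            f"partition must cover retained clusters 1..{kprime}, got {sorted(ids)}"
        )
    if set(partition.values()) - {0, 1}:
        raise PoseSpaceError("partition values must be 0 or 1")
    side = np.array([-1] + [partition[k] for k in range(1, kprime + 1)])
    assignment = side[clustering.filtered_labels]  # -1 for discarded poses
    a = chemscores[assignment == 0]
    b = chemscores[assignment == 1]
    if len(a) < 2 or len(b) < 2:
        raise PoseSpaceError(
            f"each subset needs >= 2 poses (got {len(a)} and {len(b)})"
        )
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic):  # zero variance, equal means
            statistic, p = 0.0, 1.0
    elif method == "permutation":
        res = stats.permutation_test(
            (a, b), lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent", n_resamples=n_permutations,
            alternative="two-sided", rng=np.random.default_rng(seed),
        )
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise PoseSpaceError(f"unknown method {method!r}")
    return SubsetScoreTest(
        statistic=statistic, p_value=p,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=len(a), n_b=len(b), method=method,
    )
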