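"""Compound-level analysis of the clustered pose space.

Each compound is summarized as a distribution over retained pose clusters:
its poses' chemscores (floored at zero) are summed per cluster and normalized
to unit mass.  Pairwise compound dissimilarity is the earth mover's distance
between those distributions with the cluster-centroid distances as the ground
metric — an exact optimal-transport cost, so with a metric ground distance
the result is itself a metric.  The EMD matrix is finally embedded in three
dimensions with a deterministic diffusion map (adaptive-bandwidth α-decay
kernel, diffusion time t, log-potential distances, classical MDS), which
spreads compound groups and branch structure for inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import linprog
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .cluster import ClusterGeometry, EmptyPoseSpaceError, PoseClustering


class EmbeddingError(ValueError):
    pass


@dataclass
class ScoreProfile:
    """One compound's distribution of summed chemscores over retained clusters."""

    compound_id: str
    raw: np.ndarray         # (K',) summed floored chemscores
    normalized: np.ndarray  # (K',) unit mass

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if np.any(self.normalized < -1e-12):
            raise EmbeddingError(f"{self.compound_id}: negative profile mass")
        if abs(self.normalized.sum() - 1.0) > 1e-9:
            raise EmbeddingError(f"{self.compound_id}: profile mass != 1")


@dataclass
class ScoreProfileSet:
    profiles: list[ScoreProfile]
    excluded: list[str] = field(default_factory=list)
    floored_pose_count: int = 0

    @property
    def compound_ids(self) -> list[str]:
        return [p.compound_id for p in self.profiles]

    def normalized_matrix(self) -> np.ndarray:
        return np.vstack([p.normalized for p in self.profiles])


def score_profiles(ensemble, clustering: PoseClustering) -> ScoreProfileSet:
    """Chemscore-weighted cluster occupancy per compound.

    Negative chemscores are floored at 0 before summation (transport mass
    must be nonnegative; the count of floored poses is recorded).  Compounds
    whose total floored score is zero carry no mass and are excluded with a
    warning.  ``ensemble`` may be an :class:`~posespace.io.EnsembleTable` or
    a ``(chemscores, compound_ids)`` pair aligned with the clustering rows.
    """
    clustering._require_filtered()
    if hasattr(ensemble, "sorted_poses"):
        poses = ensemble.sorted_poses()
        scores = np.array([p.chemscore for p in poses], dtype=float)
        compound_ids = np.array([p.compound_id for p in poses])
    else:
        scores, compound_ids = ensemble
        scores = np.asarray(scores, dtype=float)
        compound_ids = np.asarray(compound_ids)
    if len(scores) != len(clustering.labels):
        raise EmbeddingError("one chemscore per pose required")
    kprime = clustering.n_retained_clusters
    if kprime == 0:
        raise EmptyPoseSpaceError("no retained clusters (empty pose space)")

    floored = np.maximum(scores, 0.0)
    n_floored = int((scores < 0).sum())
    profiles: list[ScoreProfile] = []
    excluded: list[str] = []
    for cid in sorted(set(compound_ids)):
        mine = compound_ids == cid
        raw = np.zeros(kprime)
        for k in range(1, kprime + 1):
            raw[k - 1] = floored[mine & (clustering.filtered_labels == k)].sum()
        total = raw.sum()
        if total <= 0:
            excluded.append(cid)
            warnings.warn(
                f"compound {cid!r} has zero total score mass in retained "
                "clusters; excluded from profiles", stacklevel=2,
            )
            continue
        profiles.append(ScoreProfile(cid, raw=raw, normalized=raw / total))
    return ScoreProfileSet(profiles=profiles, excluded=excluded,
                           floored_pose_count=n_floored)


def emd(p: np.ndarray, q: np.ndarray, ground: np.ndarray | ClusterGeometry) -> float:
    """Exact earth mover's distance between two unit-mass histograms.

    Solves the transportation linear program
    ``min Σ_ij d_ij f_ij  s.t.  Σ_j f_ij = p_i,  Σ_i f_ij = q_j,  f ≥ 0``
    over the shared cluster index with ``d`` the centroid ground distances.
    """
    D = ground.distances if isinstance(ground, ClusterGeometry) else np.asarray(ground, float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n = len(p)
    if q.shape != (n,) or D.shape != (n, n):
        raise EmbeddingError("profile/ground-distance shape mismatch")
    if abs(p.sum() - q.sum()) > 1e-6:
        raise EmbeddingError(f"mass mismatch: {p.sum()} vs {q.sum()}")
    if np.any(p < -1e-12) or np.any(q < -1e-12):
        raise EmbeddingError("negative mass")
    # equality constraints: n row sums then n column sums (one is redundant;
    # HiGHS handles the degeneracy)
    A_rows = np.kron(np.eye(n), np.ones(n))
    A_cols = np.kron(np.ones(n), np.eye(n))
    res = linprog(
        c=D.ravel(),
        A_eq=np.vstack([A_rows, A_cols]),
        b_eq=np.concatenate([p, q]),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise EmbeddingError(f"transport LP failed: {res.message}")
    return float(res.fun)


@dataclass
class CompoundDistances:
    compound_ids: list[str]
    matrix: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.compound_ids)
        if self.matrix.shape != (n, n):
            raise EmbeddingError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise EmbeddingError("distance matrix not symmetric")


def emd_matrix(profiles: ScoreProfileSet,
               geometry: ClusterGeometry) -> CompoundDistances:
    """All pairwise compound EMDs (one LP per unordered pair)."""
    n = len(profiles.profiles)
    if n < 2:
        raise EmbeddingError(f"need >= 2 profiles, got {n}")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = emd(
                profiles.profiles[i].normalized,
                profiles.profiles[j].normalized,
                geometry,
            )
    return CompoundDistances(compound_ids=profiles.compound_ids, matrix=M)


@dataclass
class CompoundEmbedding:
    compound_ids: list[str]
    coordinates: np.ndarray  # (n, dims)
    diagnostics: dict = field(default_factory=dict)


class DiffusionMap(BaseEstimator):
    """Deterministic diffusion-map embedding of a precomputed distance matrix.

    The kernel is an adaptive-bandwidth α-decay kernel
    ``K_ij = (exp(−(d_ij/σ_i)^α) + exp(−(d_ij/σ_j)^α)) / 2`` with σ_i the
    distance to the ``knn``-th nearest neighbor; rows are normalized to a
    stochastic matrix P, powered ``t`` steps, and the −log potential of P^t
    is embedded by classical MDS.  Everything is dense and deterministic
    (no seeds): eigendecomposition with the sign of each output axis fixed
    so its largest-magnitude coordinate is positive.

    Parameters
    ----------
    n_components : output dimensionality (3 for the standard visualization).
    knn : neighbor index used for the adaptive bandwidth (default 5).
    decay : kernel decay exponent α (default 10).
    t : diffusion time, the number of Markov steps (default 3).
    """

    def __init__(self, n_components: int = 3, knn: int = 5,
                 decay: float = 10.0, t: int = 3,
                 on_disconnect: str = "warn"):
        self.n_components = n_components
        self.knn = knn
        self.decay = decay
        self.t = t
        self.on_disconnect = on_disconnect

    def fit(self, X, y=None):
        """Fit on an (n, n) symmetric distance matrix."""
        D = np.asarray(X, dtype=float)
        n = D.shape[0]
        if D.ndim != 2 or D.shape[1] != n:
            raise EmbeddingError("X must be a square distance matrix")
        if n < self.n_components + 1:
            raise EmbeddingError(
                f"need >= {self.n_components + 1} samples, got {n}"
            )
        if not np.allclose(D, D.T, atol=1e-9):
            raise EmbeddingError("distance matrix not symmetric")

        k = min(self.knn, n - 1)
        sorted_d = np.sort(D, axis=1)          # column 0 is the self-distance 0
        sigma = np.maximum(sorted_d[:, k], 1e-12)
        with np.errstate(over="ignore"):
            decayed = np.exp(-np.power(D / sigma[:, None], self.decay))
        K = 0.5 * (decayed + decayed.T)
        np.fill_diagonal(K, 1.0)

        n_comp, _ = connected_components(K > 1e-8, directed=False)
        self.n_kernel_components_ = int(n_comp)
        if n_comp > 1:
            # the log-potential stays finite across components, so the
            # embedding is still well-defined; strongly separated groups
            # disconnect the kernel by construction
            msg = (f"kernel graph has {n_comp} disconnected components; "
                   "diffusion cannot mix across them (increase knn to "
                   "connect)")
            if self.on_disconnect == "error":
                raise EmbeddingError(msg)
            warnings.warn(msg, stacklevel=2)
        P = K / K.sum(axis=1, keepdims=True)
        Pt = np.linalg.matrix_power(P, self.t)
        potential = -np.log(Pt + 1e-7)
        pot_dist = squareform(pdist(potential))
        self.embedding_, self.eigenvalues_ = _classical_mds(
            pot_dist, self.n_components
        )
        self.bandwidths_ = sigma
        self.potential_distances_ = pot_dist
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def _classical_mds(D: np.ndarray, dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS with a fixed sign convention."""
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    B = 0.5 * (B + B.T)
    vals, vecs = eigh(B, subset_by_index=(n - dims, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    flip = np.sign(coords[np.argmax(np.abs(coords), axis=0),
                          np.arange(dims)])
    flip[flip == 0] = 1.0
    return coords * flip, vals


def diffusion_embed(distances: CompoundDistances, dims: int = 3,
                    knn: int = 5, decay: float = 10.0,
                    t: int = 3) -> CompoundEmbedding:
    """Embed the compound EMD matrix in ``dims`` dimensions (see
    :class:`DiffusionMap` for the algorithm and parameters)."""
    dm = DiffusionMap(n_components=dims, knn=knn, decay=decay, t=t)
    coords = dm.fit_transform(distances.matrix)
    return CompoundEmbedding(
        compound_ids=list(distances.compound_ids),
        coordinates=coords,
        diagnostics={
            "knn": knn, "decay": decay, "t": t,
            "bandwidths": dm.bandwidths_.tolist(),
            "eigenvalues": dm.eigenvalues_.tolist(),
        },
    )


def branch_report(embedding: CompoundEmbedding,
                  distances: CompoundDistances | None = None,
                  k: int = 3, outlier_quantile: float = 0.9) -> list[dict]:
    """Rank compounds by remoteness from the main mass of the embedding.

    For each compound: the median embedding distance to all other compounds,
    its ``k`` nearest neighbors, and an outlier flag for compounds whose
    median distance strictly exceeds the ``outlier_quantile`` quantile of
    those medians.  Descriptive only — no inference is attached.
    """
    coords = np.asarray(embedding.coordinates)
    ids = embedding.compound_ids
    n = len(ids)
    D = squareform(pdist(coords))
    k = min(k, n - 1)
    medians = np.array([
        np.median(np.delete(D[i], i)) if n > 1 else 0.0 for i in range(n)
    ])
    cutoff = float(np.quantile(medians, outlier_quantile)) if n else 0.0
    report = []
    for i in range(n):
        order = np.argsort(D[i])
        neighbors = [ids[j] for j in order if j != i][:k]
        report.append({
            "compound_id": ids[i],
            "median_distance": float(medians[i]),
            "nearest_neighbors": neighbors,
            "is_outlier": bool(medians[i] > cutoff),
        })
    report.sort(key=lambda r: -r["median_distance"])
    return report
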