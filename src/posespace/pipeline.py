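"""End-to-end pose-space analysis: features → clusters → profiles → embedding."""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import (ClusterGeometry, PCAResult, PoseClusterer, PoseClustering,
                      centroid_distances, pca_reduce)
from .embed import (CompoundDistances, CompoundEmbedding, ScoreProfileSet,
                    diffusion_embed, emd_matrix, score_profiles)
from .frame import FeatureMatrix, extract_features
from .io import EnsembleTable


@dataclass
class PoseSpaceResult:
    """Everything the pipeline produces, stage by stage."""

    features: FeatureMatrix
    clustering: PoseClustering
    pca: PCAResult
    geometry: ClusterGeometry
    profiles: ScoreProfileSet
    distances: CompoundDistances
    embedding: CompoundEmbedding


def analyze_ensemble(ensemble: EnsembleTable, n_clusters: int,
                     min_count: int = 10, linkage: str = "ward",
                     encoding: str = "sincos", n_components: int = 3,
                     embed_dims: int = 3, knn: int = 5, decay: float = 10.0,
                     t: int = 3) -> PoseSpaceResult:
    """Run the full workflow on a validated ensemble.

    Stages: per-pose anchored-frame features; pooled agglomerative RMSD
    clustering cut at ``n_clusters`` with the strictly-more-than-
    ``min_count`` per-compound population filter; PCA of the encoded
    spherical coordinates; centroid distances in the first ``n_components``
    components; chemscore-sum profiles per compound; pairwise EMD under the
    centroid ground metric; deterministic diffusion-map embedding.
    """
    features = extract_features(ensemble)
    clusterer = PoseClusterer(n_clusters=n_clusters, linkage=linkage,
                              min_count=min_count)
    clusterer.fit(features)
    clustering = clusterer.clustering_
    pca = pca_reduce(features, encoding=encoding)
    geometry = centroid_distances(clustering, pca.scores,
                                  n_components=n_components)
    profiles = score_profiles(ensemble, clustering)
    distances = emd_matrix(profiles, geometry)
    embedding = diffusion_embed(distances, dims=embed_dims, knn=knn,
                                decay=decay, t=t)
    return PoseSpaceResult(features=features, clustering=clustering, pca=pca,
                           geometry=geometry, profiles=profiles,
                           distances=distances, embedding=embedding)
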