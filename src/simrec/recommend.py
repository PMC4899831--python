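"""Similarity-based medication-plan recommendation.

A new patient's encoded vector is compared with every cluster of good
responders via the generalized Mahalanobis distance; clusters are ranked
ascending and the most similar cluster's label plan is recommended.

:class:`SimilarityRecommender` composes the clustering and the metric
into one scikit-learn estimator: ``fit(X, plans)`` on training good
responders, ``predict(X)`` returns canonical plan strings, and
``decision_function(X)`` returns the confidence score (negative winning
distance) used by the evaluation ROC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .cluster import Cluster, ClusteringResult, TherapyClusterer
from .distance import SPSDMatrix, estimate_S, mahalanobis_distance

__all__ = ["Recommendation", "SimilarityRecommender", "recommend"]


@dataclass
class Recommendation:
    """Ranked clusters for one patient; ``margin`` is the runner-up
    distance minus the winner's (``None`` with a single cluster)."""

    patient_id: object
    ranked: list[tuple[int, str, float]]
    recommended_plan: str
    margin: float | None


def _rank_clusters(
    x: np.ndarray, clusters: list[Cluster], s_for: dict[int, SPSDMatrix]
) -> list[tuple[int, str, float]]:
    rows = []
    for c in clusters:
        d = mahalanobis_distance(x, c, s_for[c.cluster_id])
        rows.append((c, d))
    # deterministic tie-break on equal distance: larger cluster, then plan
    rows.sort(key=lambda cd: (cd[1], -cd[0].n_members, cd[0].label_plan))
    return [(c.cluster_id, c.label_plan, d) for c, d in rows]


def recommend(
    x: np.ndarray,
    clustering: ClusteringResult,
    S: SPSDMatrix | dict[int, SPSDMatrix],
    patient_id=None,
) -> Recommendation:
    """Rank all clusters by distance from ``x`` and recommend the winner's
    plan.  ``S`` is one shared metric or a per-cluster mapping."""
    if not clustering.clusters:
        raise ValueError("cannot recommend from an empty clustering")
    if isinstance(S, SPSDMatrix):
        s_for = {c.cluster_id: S for c in clustering.clusters}
    else:
        s_for = S
    ranked = _rank_clusters(np.asarray(x, dtype=float), clustering.clusters, s_for)
    margin = ranked[1][2] - ranked[0][2] if len(ranked) > 1 else None
    return Recommendation(patient_id, ranked, ranked[0][1], margin)


class SimilarityRecommender(BaseEstimator):
    """Cluster good responders, estimate S, recommend by nearest cluster.

    Parameters
    ----------
    method : {"supervised", "hierarchical", "kmeans"}
        Clustering strategy for the training good responders.
    n_clusters : int
        k for the unsupervised strategies (default 7).
    merge_threshold : float
        Small-cluster merging threshold (fraction of training patients).
    s_provenance : {"pooled_inverse_covariance", "identity", "per_cluster_inverse_covariance"}
        Construction of the SPSD metric.  Per-cluster metrics are offered
        for sensitivity analysis only: distances to different clusters are
        then not comparable as a single metric.
    shrinkage : float
        Shrinkage weight toward the covariance diagonal.
    random_state : int or None
        Seed for k-means++ initialization.

    Attributes
    ----------
    clusterer_ : TherapyClusterer
    clustering_ : ClusteringResult
    S_ : SPSDMatrix or dict of cluster id -> SPSDMatrix
    """

    def __init__(
        self,
        method: str = "supervised",
        n_clusters: int = 7,
        merge_threshold: float = 0.05,
        apply_merge: bool | None = None,
        s_provenance: str = "pooled_inverse_covariance",
        shrinkage: float = 0.1,
        random_state: int | None = None,
    ):
        self.method = method
        self.n_clusters = n_clusters
        self.merge_threshold = merge_threshold
        self.apply_merge = apply_merge
        self.s_provenance = s_provenance
        self.shrinkage = shrinkage
        self.random_state = random_state

    def fit(self, X, y, patient_ids=None) -> "SimilarityRecommender":
        """Fit on training good responders: X encoded features, y plans."""
        X = np.asarray(X, dtype=float)
        self.clusterer_ = TherapyClusterer(
            method=self.method,
            n_clusters=self.n_clusters,
            merge_threshold=self.merge_threshold,
            apply_merge=self.apply_merge,
            random_state=self.random_state,
        ).fit(X, y, patient_ids=patient_ids)
        self.clustering_ = self.clusterer_.result_
        labels = self.clusterer_.labels_
        if self.s_provenance == "per_cluster_inverse_covariance":
            self.S_ = {}
            for c in self.clustering_.clusters:
                mask = labels == c.cluster_id
                self.S_[c.cluster_id] = estimate_S(
                    X[mask],
                    provenance="pooled_inverse_covariance",
                    shrinkage_lambda=self.shrinkage,
                )
        else:
            self.S_ = estimate_S(
                X,
                labels,
                provenance=self.s_provenance,
                shrinkage_lambda=self.shrinkage,
            )
        return self

    def recommend(self, X, patient_ids=None) -> list[Recommendation]:
        X = np.asarray(X, dtype=float)
        ids = patient_ids if patient_ids is not None else range(len(X))
        return [
            recommend(x, self.clustering_, self.S_, patient_id=pid)
            for x, pid in zip(X, ids)
        ]

    def predict(self, X) -> np.ndarray:
        """Recommended canonical plan per row of X."""
        return np.asarray([r.recommended_plan for r in self.recommend(X)], dtype=object)

    def decision_function(self, X) -> np.ndarray:
        """Confidence score per row: negative distance to the winning
        cluster (larger = more similar)."""
        return np.asarray([-r.ranked[0][2] for r in self.recommend(X)])
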