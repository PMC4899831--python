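"""Clustering of good responders and plan labeling of clusters.

Three strategies build labeled clusters:

* ``kmeans`` — Lloyd's algorithm with seeded k-means++ initialization;
* ``hierarchical`` — agglomerative clustering, Ward linkage on Euclidean
  distances, cut at k clusters;
* ``supervised`` — one cluster per distinct medication plan (the plan is
  the class variable), followed by small-cluster merging.

Unsupervised clusters are labeled with their most frequent member plan.
Clusters holding less than 5% of the training population are absorbed,
smallest first, into the large cluster whose label plan has maximal
Jaccard similarity of drug-class sets; the worked case is a small
{ACEI, CCB, Statin} cluster merging into {ACEI, BB, CCB, Statin}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering, KMeans

from .plans import canonical_plan, plan_classes, plan_jaccard

__all__ = [
    "Cluster",
    "ClusteringResult",
    "TherapyClusterer",
    "cluster_unsupervised",
    "cluster_supervised",
    "label_cluster",
    "merge_small_clusters",
]

METHODS = ("kmeans", "hierarchical", "supervised")


@dataclass
class Cluster:
    """One labeled cluster of good responders."""

    cluster_id: int
    member_ids: list
    centroid: np.ndarray
    label_plan: str
    size_fraction: float

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusteringResult:
    """Clusters, the membership partition and the merge audit trail."""

    method: str
    clusters: list[Cluster]
    assignment: dict
    merge_log: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def label_cluster(member_plans: list[str], global_counts: Counter | None = None) -> str:
    """Most frequent plan among cluster members.

    Ties are broken by larger plan frequency in the whole training set,
    then by lexicographically smallest canonical string.
    """
    if not member_plans:
        raise ValueError("label_cluster requires a nonempty cluster")
    counts = Counter(canonical_plan(p) for p in member_plans)
    global_counts = global_counts or Counter()
    return min(
        counts,
        key=lambda p: (-counts[p], -global_counts.get(p, 0), p),
    )


def _build_clusters(
    X: np.ndarray,
    labels: np.ndarray,
    plans: np.ndarray,
    ids: np.ndarray,
    global_counts: Counter,
    fixed_plans: dict[int, str] | None = None,
) -> list[Cluster]:
    clusters = []
    n = len(labels)
    for cid in sorted(set(labels.tolist())):
        mask = labels == cid
        plan = (
            fixed_plans[cid]
            if fixed_plans is not None
            else label_cluster(list(plans[mask]), global_counts)
        )
        clusters.append(
            Cluster(
                cluster_id=int(cid),
                member_ids=list(ids[mask]),
                centroid=X[mask].mean(axis=0),
                label_plan=plan,
                size_fraction=float(mask.sum()) / n,
            )
        )
    return clusters


def merge_small_clusters(
    result: ClusteringResult, threshold: float = 0.05
) -> ClusteringResult:
    """Absorb sub-threshold clusters into plan-similar large clusters.

    Iteratively, the smallest cluster below ``threshold`` (of the training
    population) is absorbed into the large cluster whose label plan has
    maximal Jaccard similarity with its own; ties prefer a strict superset
    plan, then the largest cluster, then the lexicographically smallest
    plan.  Absorbed members adopt the absorber's label; centroids are
    recomputed as member means.  If no large cluster exists the smallest
    pair is merged instead.  Terminates when every cluster holds at least
    ``threshold`` of the population or one cluster remains.
    """
    clusters = [
        replace(c, member_ids=list(c.member_ids), centroid=c.centroid.copy())
        for c in result.clusters
    ]
    merge_log = list(result.merge_log)
    total = sum(c.n_members for c in clusters)

    def pick_target(small: Cluster, candidates: list[Cluster]) -> Cluster:
        small_set = plan_classes(small.label_plan)

        def key(c: Cluster):
            sim = plan_jaccard(small.label_plan, c.label_plan)
            superset = plan_classes(c.label_plan) >= small_set
            return (-sim, not superset, -c.n_members, c.label_plan)

        return min(candidates, key=key)

    while len(clusters) > 1:
        small_ones = [c for c in clusters if c.size_fraction < threshold]
        if not small_ones:
            break
        small = min(small_ones, key=lambda c: (c.n_members, c.label_plan, c.cluster_id))
        large = [c for c in clusters if c.size_fraction >= threshold and c is not small]
        if large:
            target = pick_target(small, large)
        else:
            # documented fallback: no large cluster yet -> merge the smallest pair
            target = min(
                (c for c in clusters if c is not small),
                key=lambda c: (c.n_members, c.label_plan, c.cluster_id),
            )
        n1, n2 = target.n_members, small.n_members
        target.centroid = (n1 * target.centroid + n2 * small.centroid) / (n1 + n2)
        target.member_ids.extend(small.member_ids)
        target.size_fraction = (n1 + n2) / total
        merge_log.append(
            (small.label_plan, target.label_plan, plan_jaccard(small.label_plan, target.label_plan))
        )
        clusters.remove(small)

    assignment = {pid: c.cluster_id for c in clusters for pid in c.member_ids}
    return ClusteringResult(result.method, clusters, assignment, merge_log)


class TherapyClusterer(BaseEstimator):
    """Clusters (good-responder) patients and labels clusters with plans.

    Parameters
    ----------
    method : {"kmeans", "hierarchical", "supervised"}
    n_clusters : int
        k for the unsupervised methods (k=7 by default; supervised
        clustering derives its count from the distinct plans).
    merge_threshold : float
        Minimum cluster size as a fraction of the training population.
    apply_merge : bool or None
        Whether to run small-cluster merging.  ``None`` (default) merges
        after supervised clustering only.
    random_state : int or None
        Seed for k-means++ initialization.

    Attributes
    ----------
    result_ : ClusteringResult
    labels_ : ndarray of cluster ids per training row
    """

    def __init__(
        self,
        method: str = "supervised",
        n_clusters: int = 7,
        merge_threshold: float = 0.05,
        apply_merge: bool | None = None,
        random_state: int | None = None,
    ):
        self.method = method
        self.n_clusters = n_clusters
        self.merge_threshold = merge_threshold
        self.apply_merge = apply_merge
        self.random_state = random_state

    def fit(self, X: np.ndarray, y, patient_ids=None) -> "TherapyClusterer":
        """Fit on feature matrix X with medication plans y."""
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        X = np.asarray(X, dtype=float)
        plans = np.asarray([canonical_plan(p) for p in y], dtype=object)
        ids = (
            np.asarray(patient_ids, dtype=object)
            if patient_ids is not None
            else np.arange(len(X))
        )
        global_counts = Counter(plans.tolist())

        if self.method == "supervised":
            plan_ids = {p: i for i, p in enumerate(sorted(set(plans.tolist())))}
            labels = np.array([plan_ids[p] for p in plans])
            fixed = {i: p for p, i in plan_ids.items()}
            clusters = _build_clusters(X, labels, plans, ids, global_counts, fixed)
        else:
            k = self.n_clusters
            if k < 2:
                raise ValueError("n_clusters must be >= 2")
            if len(np.unique(X, axis=0)) < k:
                raise ValueError("need at least n_clusters distinct points")
            if self.method == "kmeans":
                model = KMeans(
                    n_clusters=k,
                    init="k-means++",
                    n_init=10,
                    random_state=self.random_state,
                )
            else:
                model = AgglomerativeClustering(n_clusters=k, linkage="ward")
            labels = model.fit_predict(X)
            clusters = _build_clusters(X, labels, plans, ids, global_counts)

        assignment = {pid: int(cid) for pid, cid in zip(ids, labels)}
        result = ClusteringResult(self.method, clusters, assignment)
        do_merge = (
            self.apply_merge
            if self.apply_merge is not None
            else self.method == "supervised"
        )
        if do_merge:
            result = merge_small_clusters(result, self.merge_threshold)
        self.result_ = result
        self.labels_ = np.array([result.assignment[pid] for pid in ids])
        return self


def cluster_unsupervised(
    X: np.ndarray,
    plans,
    method: str = "kmeans",
    k: int = 7,
    seed: int | None = None,
    patient_ids=None,
) -> ClusteringResult:
    """K-means or Ward hierarchical clustering at k clusters, plan-labeled."""
    if method not in ("kmeans", "hierarchical"):
        raise ValueError("method must be 'kmeans' or 'hierarchical'")
    est = TherapyClusterer(method=method, n_clusters=k, random_state=seed)
    return est.fit(X, plans, patient_ids=patient_ids).result_


def cluster_supervised(
    X: np.ndarray,
    plans,
    merge_threshold: float = 0.05,
    patient_ids=None,
) -> ClusteringResult:
    """One cluster per distinct plan, then small-cluster merging."""
    est = TherapyClusterer(method="supervised", merge_threshold=merge_threshold)
    return est.fit(X, plans, patient_ids=patient_ids).result_
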