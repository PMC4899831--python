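"""Clustering strategies, cluster labeling and small-cluster merging."""

from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import simrec
from simrec.cluster import (
    Cluster,
    ClusteringResult,
    TherapyClusterer,
    cluster_supervised,
    cluster_unsupervised,
    label_cluster,
    merge_small_clusters,
)
from simrec.features import CohortEncoder
from simrec.plans import plan_jaccard
from tests.conftest import extracts_of


def _encoded_good_responders(syn):
    cohort, _, _ = simrec.build_cohort(extracts_of(syn))
    enc = CohortEncoder().fit(cohort)
    mask = (cohort["response"] == "good") & (cohort["plan"] != "")
    sub = cohort[mask]
    return enc.transform(sub), sub["plan"].to_numpy(), sub["patient_id"].to_numpy()


@pytest.mark.parametrize("method", ["kmeans", "hierarchical"])
def test_well_separated_planted_groups_recovered_perfectly(method):
    """Three latent blobs at separation 10 SD: ARI vs planted groups = 1.0
    when clustering the continuous block that carries the separation."""
    cfg = simrec.default_config(
        n_patients=600, seed=21, n_latent_groups=3, group_separation=10.0
    )
    syn = simrec.generate_cohort(cfg)
    X, plans, ids = _encoded_good_responders(syn)
    X = X[:, :8]  # the continuous block; the flag block is Bernoulli noise
    result = cluster_unsupervised(X, plans, method=method, k=3, seed=0, patient_ids=ids)
    gt = syn.ground_truth.set_index("patient_id")
    planted = gt.loc[list(result.assignment), "latent_group"].to_numpy()
    got = np.array([result.assignment[p] for p in result.assignment])
    assert adjusted_rand_score(planted, got) == 1.0


def test_k_equal_n_gives_zero_within_cluster_scatter():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3))
    plans = ["ACEI"] * 12
    result = cluster_unsupervised(X, plans, method="hierarchical", k=12)
    wss = 0.0
    for c in result.clusters:
        members = [i for i, cid in result.assignment.items() if cid == c.cluster_id]
        wss += sum(np.sum((X[i] - c.centroid) ** 2) for i in members)
    assert wss == pytest.approx(0.0, abs=1e-12)


def test_kmeans_is_deterministic_for_a_fixed_seed(planted_synthetic):
    X, plans, ids = _encoded_good_responders(planted_synthetic)
    a = cluster_unsupervised(X, plans, method="kmeans", k=4, seed=3, patient_ids=ids)
    b = cluster_unsupervised(X, plans, method="kmeans", k=4, seed=3, patient_ids=ids)
    assert a.assignment == b.assignment
    for ca, cb in zip(a.clusters, b.clusters):
        np.testing.assert_array_equal(ca.centroid, cb.centroid)
        assert ca.label_plan == cb.label_plan


def test_supervised_one_cluster_per_plan_no_merge_when_large():
    X = np.vstack([np.zeros((30, 2)), np.ones((20, 2))])
    plans = ["ACEI"] * 30 + ["BB"] * 20
    result = cluster_supervised(X, plans)
    assert result.n_clusters == 2
    assert result.merge_log == []
    assert {c.label_plan for c in result.clusters} == {"ACEI", "BB"}


def test_supervised_clusters_are_plan_pure_before_merging(planted_synthetic):
    X, plans, ids = _encoded_good_responders(planted_synthetic)
    est = TherapyClusterer(method="supervised", apply_merge=False).fit(
        X, plans, patient_ids=ids
    )
    plan_of = dict(zip(ids, plans))
    for c in est.result_.clusters:
        assert {plan_of[m] for m in c.member_ids} == {c.label_plan}


def test_label_cluster_modal_and_tie_breaks():
    assert label_cluster(["ACEI+BB"] * 5 + ["ACEI"] * 3) == "ACEI+BB"
    # tie broken by global frequency, then lexicographic
    global_counts = Counter({"BB": 10, "ACEI": 4})
    assert label_cluster(["ACEI", "ACEI", "BB", "BB"], global_counts) == "BB"
    assert label_cluster(["ACEI", "ACEI", "BB", "BB"]) == "ACEI"
    assert label_cluster(["CCB"]) == "CCB"


def _result_from_sizes(sizes_plans, total=None):
    total = total or sum(n for n, _ in sizes_plans)
    nxt = iter(range(10**6))
    clusters = [
        Cluster(i, [next(nxt) for _ in range(n)], np.zeros(2), plan, n / total)
        for i, (n, plan) in enumerate(sizes_plans)
    ]
    assignment = {m: c.cluster_id for c in clusters for m in c.member_ids}
    return ClusteringResult("supervised", clusters, assignment)


def test_merge_reproduces_the_superset_worked_example():
    """A small ACEI+CCB+Statin cluster is absorbed by the large
    ACEI+BB+CCB+Statin cluster (its maximal-Jaccard superset)."""
    result = _result_from_sizes(
        [
            (50, "ACEI+BB+CCB+Statin"),
            (30, "ACEI+BB"),
            (16, "BB+Statin"),
            (4, "ACEI+CCB+Statin"),
        ]
    )
    merged = merge_small_clusters(result, threshold=0.05)
    assert merged.merge_log == [("ACEI+CCB+Statin", "ACEI+BB+CCB+Statin", 0.75)]
    winner = [c for c in merged.clusters if c.label_plan == "ACEI+BB+CCB+Statin"][0]
    assert winner.n_members == 54


def test_merge_is_a_noop_when_all_clusters_are_large():
    result = _result_from_sizes([(60, "ACEI"), (40, "BB")])
    merged = merge_small_clusters(result, threshold=0.05)
    assert merged.merge_log == []
    assert [c.n_members for c in merged.clusters] == [60, 40]


def test_merge_picks_the_brute_force_best_target_on_randomized_configs():
    """The greedy absorption target always equals the exhaustive-enumeration
    argmax of plan Jaccard (with the documented tie-breaks)."""
    rng = np.random.default_rng(42)
    plans = simrec.all_plans()
    for _ in range(100):
        k = rng.integers(3, 9)
        chosen = list(rng.choice(plans, size=k, replace=False))
        sizes = rng.integers(1, 60, size=k)
        total = int(sizes.sum())
        result = _result_from_sizes(list(zip(sizes.tolist(), chosen)), total)
        small_ones = [c for c in result.clusters if c.size_fraction < 0.05]
        large = [c for c in result.clusters if c.size_fraction >= 0.05]
        if not small_ones or not large:
            continue
        small = min(small_ones, key=lambda c: (c.n_members, c.label_plan, c.cluster_id))

        def brute_key(c):
            sim = plan_jaccard(small.label_plan, c.label_plan)
            superset = set(c.label_plan.split("+")) >= set(small.label_plan.split("+"))
            return (-sim, not superset, -c.n_members, c.label_plan)

        expected_target = min(large, key=brute_key)
        merged = merge_small_clusters(result, threshold=0.05)
        first_small, first_target, _ = merged.merge_log[0]
        assert first_small == small.label_plan
        assert first_target == expected_target.label_plan


def test_merge_terminates_and_enforces_the_size_floor():
    rng = np.random.default_rng(7)
    plans = simrec.all_plans()
    for _ in range(25):
        k = int(rng.integers(2, 12))
        chosen = list(rng.choice(plans, size=k, replace=False))
        sizes = rng.integers(1, 30, size=k).tolist()
        result = _result_from_sizes(list(zip(sizes, chosen)))
        merged = merge_small_clusters(result, threshold=0.05)
        total = sum(sizes)
        # partition preserved
        assert sum(c.n_members for c in merged.clusters) == total
        assert len(merged.assignment) == total
        # merging only removes clusters, within initial-count - 1 steps
        assert len(merged.merge_log) == len(result.clusters) - len(merged.clusters)
        # floor holds or a single cluster remains
        if len(merged.clusters) > 1:
            assert min(c.size_fraction for c in merged.clusters) >= 0.05


def test_merged_centroids_are_member_means():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 3))
    plans = (
        ["ACEI+BB"] * 30 + ["ACEI"] * 8 + ["ACEI+CCB"] * 2
    )
    est = TherapyClusterer(method="supervised", merge_threshold=0.25).fit(X, plans)
    for c in est.result_.clusters:
        np.testing.assert_allclose(
            c.centroid, X[list(c.member_ids)].mean(axis=0), atol=1e-12
        )


def test_pre_merge_cluster_count_equals_distinct_plans(planted_synthetic):
    X, plans, ids = _encoded_good_responders(planted_synthetic)
    est = TherapyClusterer(method="supervised", apply_merge=False).fit(X, plans)
    assert est.result_.n_clusters == len(set(plans.tolist()))
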