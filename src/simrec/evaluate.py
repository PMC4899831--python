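"""Validation protocol: repeated stratified splits and Table-style metrics.

Ten (by default) seeded stratified 70/30 splits of the labeled cohort:
the training split is clustered per method, every test patient receives a
recommendation, and the binary outcome is *plan match among good
responders* — outcome 1 iff the patient responded well AND the
recommended plan equals the observed plan.  The continuous confidence
score is the negative distance to the winning cluster.  Specificity,
sensitivity, F1 and accuracy are reported at the first cut point (the
50th score percentile); the AUC integrates the full ROC and is
cross-checked against the Mann-Whitney formulation.

Also provides plan-frequency-by-EF-interval summaries over the bins
[0,10), [10,20), [20,30), [30,40), [40,50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedShuffleSplit

from .features import CohortEncoder
from .recommend import Recommendation, SimilarityRecommender

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "UndefinedMetricError",
    "split_runs",
    "score_patient",
    "auc_trapezoid",
    "auc_mann_whitney",
    "compute_metrics",
    "evaluate_methods",
    "plan_frequency_by_ef",
]

EF_BINS: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class outcomes)."""


@dataclass
class EvaluationConfig:
    """Protocol parameters; defaults mirror the study design."""

    n_runs: int = 10
    train_fraction: float = 0.7
    methods: tuple[str, ...] = ("supervised", "hierarchical", "kmeans")
    cut_points: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0, 90.0)
    seed: int = 0
    n_clusters: int = 7
    merge_threshold: float = 0.05
    s_provenance: str = "pooled_inverse_covariance"
    shrinkage: float = 0.1

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        cps = list(self.cut_points)
        if cps != sorted(cps) or cps[0] != 50.0:
            raise ValueError("cut_points must ascend and start at 50")


@dataclass
class EvaluationReport:
    """Mean/SD metrics per method, per-run counts and ROC points."""

    summary: pd.DataFrame
    per_run: pd.DataFrame
    roc_points: pd.DataFrame
    config: EvaluationConfig = field(repr=False, default=None)


def split_runs(labels, config: EvaluationConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified train/test splits (stratified on response label).

    Train/test are disjoint and exhaustive in every run; with n = 1386
    and train_fraction = 0.7 the sizes are exactly 970 / 416.
    """
    config.validate()
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cohort is empty")
    splitter = StratifiedShuffleSplit(
        n_splits=config.n_runs,
        train_size=config.train_fraction,
        random_state=config.seed,
    )
    try:
        return [
            (train, test) for train, test in splitter.split(np.zeros(len(labels)), labels)
        ]
    except ValueError as exc:  # pragma: no cover - sklearn message passthrough
        raise ValueError(f"cohort too small for stratified splitting: {exc}") from exc


def score_patient(
    recommendation: Recommendation, actual_plan: str, actual_response: str
) -> tuple[int, float]:
    """Binary outcome and confidence score for one test patient.

    Outcome is 1 iff the patient was a good responder and the recommended
    plan equals the observed plan (canonical string equality); the score
    is the negative winning distance (larger = more confident).
    """
    outcome = int(
        actual_response == "good"
        and recommendation.recommended_plan == actual_plan
    )
    return outcome, -recommendation.ranked[0][2]


def _roc_curve(outcomes: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC points from thresholding the score at every distinct value
    (descending), plus the (0,0) and (1,1) endpoints."""
    order = np.argsort(-scores, kind="stable")
    y = outcomes[order]
    s = scores[order]
    distinct = np.r_[np.diff(s) != 0, True]  # last duplicate of each value
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return fpr, tpr


def auc_trapezoid(outcomes, scores) -> float:
    """Trapezoidal area under the ROC traced over all distinct scores."""
    outcomes = np.asarray(outcomes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(outcomes)) < 2:
        raise UndefinedMetricError("AUC undefined: outcomes are single-class")
    fpr, tpr = _roc_curve(outcomes, scores)
    return float(np.trapezoid(tpr, fpr))


def auc_mann_whitney(outcomes, scores) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    outcomes = np.asarray(outcomes, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(outcomes.sum())
    n_neg = len(outcomes) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: outcomes are single-class")
    ranks = rankdata(scores)
    u = ranks[outcomes == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    outcomes, scores, predictions, cut_points=(50.0,)
) -> dict[str, float]:
    """Confusion metrics at the given decision rule plus the score AUC.

    ``predictions`` is the binary decision per patient (here: score at or
    above the first cut-point percentile).  Returns specificity = TN/(TN+FP),
    sensitivity = TP/(TP+FN), F1 = 2PR/(P+R), accuracy, and the AUC
    (trapezoidal; asserted equal to the Mann-Whitney form to 1e-9).
    """
    outcomes = np.asarray(outcomes, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    tp = int(((outcomes == 1) & (predictions == 1)).sum())
    fp = int(((outcomes == 0) & (predictions == 1)).sum())
    tn = int(((outcomes == 0) & (predictions == 0)).sum())
    fn = int(((outcomes == 1) & (predictions == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    acc = (tp + tn) / len(outcomes)
    auc = auc_trapezoid(outcomes, scores)
    auc_mw = auc_mann_whitney(outcomes, scores)
    assert abs(auc - auc_mw) < 1e-9, "trapezoid and Mann-Whitney AUC diverge"
    return {
        "specificity": spec,
        "sensitivity": sens,
        "f1": f1,
        "accuracy": acc,
        "auc": auc,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def _predictions_at_cut(scores: np.ndarray, cut_point: float) -> np.ndarray:
    threshold = np.percentile(scores, cut_point)
    return (scores >= threshold).astype(int)


def evaluate_methods(
    cohort: pd.DataFrame, config: EvaluationConfig | None = None
) -> EvaluationReport:
    """Run the full protocol on a labeled cohort.

    Per run and method: fit the encoder on the training split, cluster the
    training good responders (untreated patients excluded), recommend for
    every treated test patient, and compute the metrics.  Fully
    deterministic for a fixed config and seed.
    """
    config = config or EvaluationConfig()
    config.validate()
    cohort = cohort.reset_index(drop=True)
    treated = cohort["plan"].astype(str) != ""
    splits = split_runs(cohort["response"].to_numpy(), config)

    per_run_rows = []
    roc_rows = []
    for run, (train_idx, test_idx) in enumerate(splits):
        train = cohort.iloc[train_idx]
        test = cohort.iloc[test_idx[treated.to_numpy()[test_idx]]]
        encoder = CohortEncoder().fit(train)
        fit_mask = (train["response"] == "good") & (train["plan"].astype(str) != "")
        X_fit = encoder.transform(train[fit_mask])
        plans_fit = train.loc[fit_mask, "plan"].to_numpy()
        X_test = encoder.transform(test)
        for method in config.methods:
            model = SimilarityRecommender(
                method=method,
                n_clusters=config.n_clusters,
                merge_threshold=config.merge_threshold,
                s_provenance=config.s_provenance,
                shrinkage=config.shrinkage,
                random_state=config.seed + run,
            ).fit(X_fit, plans_fit)
            recs = model.recommend(X_test, patient_ids=test["patient_id"].to_numpy())
            pairs = [
                score_patient(rec, plan, resp)
                for rec, plan, resp in zip(
                    recs, test["plan"].to_numpy(), test["response"].to_numpy()
                )
            ]
            outcomes = np.array([p[0] for p in pairs])
            scores = np.array([p[1] for p in pairs])
            predictions = _predictions_at_cut(scores, config.cut_points[0])
            row = compute_metrics(outcomes, scores, predictions, config.cut_points)
            row.update(method=method, run=run, n_test=len(test))
            per_run_rows.append(row)
            for cp in config.cut_points:
                pred_cp = _predictions_at_cut(scores, cp)
                tpr = pred_cp[outcomes == 1].mean() if (outcomes == 1).any() else 0.0
                fpr = pred_cp[outcomes == 0].mean() if (outcomes == 0).any() else 0.0
                roc_rows.append(
                    {"method": method, "run": run, "cut_point": cp, "fpr": fpr, "tpr": tpr}
                )

    per_run = pd.DataFrame(per_run_rows)
    metrics = ["specificity", "sensitivity", "f1", "accuracy", "auc"]
    summary = (
        per_run.groupby("method", sort=False)[metrics]
        .agg(["mean", "std"])
        .reindex(list(config.methods))
    )
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    roc_points = pd.DataFrame(roc_rows)
    return EvaluationReport(summary.reset_index(), per_run, roc_points, config)


def plan_frequency_by_ef(
    cohort: pd.DataFrame, ef_bins=EF_BINS, top: int = 5
) -> pd.DataFrame:
    """Top plans by count per index-EF interval (half-open bins; EF = 10
    falls in [10, 20)).  Empty bins are emitted with zero rows."""
    edges = list(ef_bins)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = cohort[(cohort["index_ef"] >= lo) & (cohort["index_ef"] < hi)]
        counts = (
            sub[sub["plan"].astype(str) != ""]["plan"]
            .value_counts()
            .sort_values(ascending=False)
        )
        for rank, (plan, cnt) in enumerate(counts.head(top).items(), start=1):
            rows.append(
                {
                    "ef_bin": f"[{lo:g},{hi:g})",
                    "rank": rank,
                    "plan": plan,
                    "count": int(cnt),
                }
            )
    return pd.DataFrame(rows, columns=["ef_bin", "rank", "plan", "count"])


def plot_plan_frequency(table: pd.DataFrame, path) -> None:
    """Optional bar chart of a :func:`plan_frequency_by_ef` table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = table["ef_bin"].unique()
    fig, axes = plt.subplots(1, max(len(bins), 1), figsize=(3.2 * max(len(bins), 1), 3.5))
    axes = np.atleast_1d(axes)
    for ax, b in zip(axes, bins):
        sub = table[table["ef_bin"] == b]
        ax.bar(range(len(sub)), sub["count"])
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["plan"], rotation=60, ha="right", fontsize=7)
        ax.set_title(f"EF {b}")
        ax.set_ylabel("patients")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
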