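"""Unsupervised diagnostic evaluation of mechanism profiles.

Samples are clustered from their mechanism-score vectors alone (no
labels enter the clustering); cluster quality against the clinical
truth is summarised by the F-accuracy (harmonic-mean precision/recall
of the majority-mapped two-way partition).  A cross-validated AUC from
a fixed nearest-centroid scorer and a feature-permutation empirical p
(random same-sized mechanism subsets) complete the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import MechanismProfile

__all__ = [
    "CLUSTER_ALGORITHMS",
    "ClusteringResult",
    "cluster_samples",
    "f_accuracy",
    "AUCResult",
    "cv_auc",
    "feature_permutation_p",
    "pam",
]

CLUSTER_ALGORITHMS = (
    "ward-euclidean",
    "average-euclidean",
    "centroid-correlation",
    "centroid-correlation-standardized",
    "pam-k2",
)


def _pam_assign(dist: np.ndarray, medoids: Sequence[int]) -> np.ndarray:
    return np.asarray(medoids)[np.argmin(dist[:, list(medoids)], axis=1)]


def _pam_cost(dist: np.ndarray, medoids: Sequence[int]) -> float:
    return float(dist[:, list(medoids)].min(axis=1).sum())


def pam(
    dist: np.ndarray,
    k: int,
    seed: int | None = None,
    exhaustive_limit: int = 300_000,
) -> tuple[np.ndarray, list[int]]:
    """k-medoids partitioning around medoids on a dissimilarity matrix.

    When the number of candidate medoid sets C(n, k) is below
    ``exhaustive_limit`` the exact optimum of the PAM objective (total
    dissimilarity of points to their nearest medoid) is found by
    enumeration; otherwise a greedy BUILD initialisation followed by
    full SWAP descent to a local optimum is used.  Returns (labels in
    0..k-1, medoid indices).
    """
    from itertools import combinations
    from math import comb

    n = dist.shape[0]
    if not (1 <= k <= n):
        raise ValueError("k must be between 1 and n")
    if np.allclose(dist, 0):
        raise ValueError("all pairwise dissimilarities are zero; profiles degenerate")

    if comb(n, k) <= exhaustive_limit:
        best, best_cost = None, np.inf
        for cand in combinations(range(n), k):
            c = _pam_cost(dist, cand)
            if c < best_cost - 1e-12:
                best, best_cost = cand, c
        medoids = list(best)
    else:
        rng = np.random.default_rng(seed)
        # BUILD: greedy; start from the most central point
        medoids = [int(np.argmin(dist.sum(axis=0)))]
        while len(medoids) < k:
            current = dist[:, medoids].min(axis=1)
            gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        # SWAP descent
        improved = True
        while improved:
            improved = False
            cost = _pam_cost(dist, medoids)
            for i, m in enumerate(list(medoids)):
                for h in rng.permutation(n):
                    if h in medoids:
                        continue
                    trial = medoids.copy()
                    trial[i] = int(h)
                    c = _pam_cost(dist, trial)
                    if c < cost - 1e-12:
                        medoids, cost, improved = trial, c, True
    medoids = sorted(int(m) for m in medoids)
    assign = _pam_assign(dist, medoids)
    labels = np.searchsorted(medoids, assign)
    return labels, medoids


@dataclass
class ClusteringResult:
    algorithm: str
    assignment: pd.Series  # sample id -> cluster label (0/1/...)
    mapped: pd.Series  # sample id -> predicted class label
    confusion: pd.DataFrame
    f_accuracy: float
    misclassified: list[str] = field(default_factory=list)


def _distances(x: np.ndarray, metric: str, standardize: bool) -> np.ndarray:
    if standardize:
        sd = x.std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant sample profile; cannot standardize")
        x = (x - x.mean(axis=1, keepdims=True)) / sd
    d = pdist(x, metric=metric)
    if not np.any(d > 0):
        raise ValueError("all samples identical; distances degenerate")
    return d


def cluster_samples(
    profile: MechanismProfile,
    truth: pd.Series,
    algorithm: str = "ward-euclidean",
    positive_class: str | None = None,
    k: int = 2,
    seed: int | None = None,
) -> ClusteringResult:
    """Unsupervised two-way partition of samples, scored against truth.

    Hierarchical algorithms use the first two-way partition (the tree
    cut at k clusters); ``pam-k2`` is k-medoids on euclidean distances.
    Clusters are mapped to truth labels by majority (ties resolved to
    maximise accuracy) before the confusion table and F-accuracy.
    """
    if algorithm not in CLUSTER_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {CLUSTER_ALGORITHMS}")
    x = profile.scores.to_numpy().T  # samples x mechanisms
    samples = profile.sample_ids
    truth = truth.reindex(samples)
    if truth.isna().any():
        raise ValueError("truth labels missing for some samples")

    if algorithm == "ward-euclidean":
        labels = fcluster(linkage(_distances(x, "euclidean", False), "ward"), k, "maxclust")
    elif algorithm == "average-euclidean":
        labels = fcluster(linkage(_distances(x, "euclidean", False), "average"), k, "maxclust")
    elif algorithm == "centroid-correlation":
        labels = fcluster(linkage(_distances(x, "correlation", False), "centroid"), k, "maxclust")
    elif algorithm == "centroid-correlation-standardized":
        labels = fcluster(linkage(_distances(x, "correlation", True), "centroid"), k, "maxclust")
    else:  # pam-k2
        d = squareform(_distances(x, "euclidean", False))
        labels, _ = pam(d, k=k, seed=seed)
    labels = np.asarray(labels)
    labels = labels - labels.min()

    classes = truth.unique().tolist()
    if positive_class is None:
        positive_class = classes[0]
    mapped = _majority_map(labels, truth.to_numpy(), classes)
    assignment = pd.Series(labels, index=samples, name="cluster")
    mapped_s = pd.Series(mapped, index=samples, name="predicted")
    confusion = pd.crosstab(mapped_s, truth, rownames=["predicted"], colnames=["truth"])
    fa = f_accuracy(mapped_s, truth, positive_class)
    mis = [s for s in samples if mapped_s[s] != truth[s]]
    return ClusteringResult(algorithm, assignment, mapped_s, confusion, fa, mis)


def _majority_map(labels: np.ndarray, truth: np.ndarray, classes: list) -> np.ndarray:
    """Map cluster ids to truth labels by within-cluster majority.

    If the majority rule collapses two clusters onto one label with two
    truth classes, the accuracy-maximising bijection is used instead.
    """
    uniq = np.unique(labels)
    mapping = {}
    for c in uniq:
        members = truth[labels == c]
        vals, counts = np.unique(members, return_counts=True)
        mapping[c] = vals[np.argmax(counts)]
    if len(classes) == 2 and len(uniq) == 2 and len(set(mapping.values())) == 1:
        a, b = uniq
        best, best_acc = None, -1.0
        for m in ({a: classes[0], b: classes[1]}, {a: classes[1], b: classes[0]}):
            acc = float(np.mean([m[l] == t for l, t in zip(labels, truth)]))
            if acc > best_acc:
                best, best_acc = m, acc
        mapping = best
    return np.asarray([mapping[l] for l in labels])


def f_accuracy(predicted: pd.Series, truth: pd.Series, positive_class) -> float:
    """Harmonic mean of precision and recall for the positive class (F1).

    With no predicted and no true positives the partition is vacuously
    perfect on that class and 1.0 is returned; predicted positives
    absent while true positives exist gives 0.0.
    """
    pred_pos = (predicted == positive_class).to_numpy()
    true_pos = (truth == positive_class).to_numpy()
    tp = int(np.sum(pred_pos & true_pos))
    if not pred_pos.any() and not true_pos.any():
        return 1.0
    if tp == 0:
        return 0.0
    precision = tp / pred_pos.sum()
    recall = tp / true_pos.sum()
    return 2 * precision * recall / (precision + recall)


def accuracy(predicted: pd.Series, truth: pd.Series) -> float:
    """Plain agreement fraction (alternative to the F-accuracy)."""
    return float((predicted.to_numpy() == truth.to_numpy()).mean())


@dataclass
class AUCResult:
    mean_auc: float
    per_run: np.ndarray
    folds: int
    runs: int
    seed: int | None
    oof_scores: pd.Series | None = None  # out-of-fold scores of the first run
    p_empirical: float | None = None


def _nearest_centroid_scores(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, positive
) -> np.ndarray:
    """Continuous score: distance to negative centroid minus distance to
    positive centroid (higher = more positive-like)."""
    pos = x_train[y_train == positive].mean(axis=0)
    neg = x_train[y_train != positive].mean(axis=0)
    d_pos = np.linalg.norm(x_test - pos, axis=1)
    d_neg = np.linalg.norm(x_test - neg, axis=1)
    return d_neg - d_pos


def cv_auc(
    profile: MechanismProfile,
    truth: pd.Series,
    positive_class,
    folds: int = 5,
    runs: int = 100,
    seed: int | None = None,
) -> AUCResult:
    """Mean ROC AUC over repeated stratified k-fold cross-validation.

    The out-of-fold score is produced by a fixed nearest-centroid
    scorer in mechanism space — parameter-free, so the repeated CV
    measures the separability of the profile subset rather than any
    classifier tuning.  Deterministic given the seed.
    """
    x = profile.scores.to_numpy().T
    y = truth.reindex(profile.sample_ids).to_numpy()
    n_min = min(np.sum(y == positive_class), np.sum(y != positive_class))
    if n_min < folds:
        import logging

        logging.getLogger(__name__).warning(
            "smallest class (%d) < folds (%d); reducing folds", n_min, folds
        )
        folds = max(2, int(n_min))
    rng = np.random.default_rng(seed)
    aucs = np.empty(runs)
    y_bin = (y == positive_class).astype(int)
    oof_first = None
    for r in range(runs):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        scores = np.empty(len(y))
        for tr, te in skf.split(x, y_bin):
            scores[te] = _nearest_centroid_scores(x[tr], y[tr], x[te], positive_class)
        aucs[r] = roc_auc_score(y_bin, scores)
        if r == 0:
            oof_first = pd.Series(scores, index=profile.sample_ids, name="oof_score")
    return AUCResult(float(aucs.mean()), aucs, folds, runs, seed, oof_first)


def feature_permutation_p(
    observed_metric: float,
    profile_full: MechanismProfile,
    signature_size: int,
    metric_fn: Callable[[MechanismProfile], float],
    n_resample: int = 1000,
    seed: int | None = None,
) -> float:
    """Empirical p of a metric against random same-sized mechanism subsets.

    Draws ``n_resample`` random subsets of ``signature_size`` mechanisms
    from the full profile, recomputes the metric on each, and returns
    ``(1 + #{random >= observed}) / (n_resample + 1)``.
    """
    ids = np.asarray(profile_full.mechanism_ids)
    if signature_size > len(ids):
        raise ValueError("signature larger than the mechanism universe")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_resample):
        sub = profile_full.subset(rng.choice(ids, size=signature_size, replace=False))
        if metric_fn(sub) >= observed_metric:
            b += 1
    return (1 + b) / (n_resample + 1)
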