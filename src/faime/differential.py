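"""Deregulated-mechanism calling and cross-dataset signature assembly.

For each mechanism the per-sample scores are compared between two
phenotype groups with a Z-test (paired or unpaired), an empirical p is
obtained by jointly re-permuting the phenotype labels and recomputing
every mechanism's statistic (which preserves the between-mechanism
correlation structure inherited from shared genes), and the analytic
p-values are adjusted with the Benjamini-Yekutieli step-up, which is
valid under arbitrary dependence.  Significant GO terms can be pruned
to one representative per connected region of the ontology graph, and
signatures from independent datasets can be intersected, with the
significance of the overlap assessed by resampling same-sized term sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core import MechanismProfile
from .io import SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ztest_mechanisms",
    "permutation_null",
    "test_mechanisms",
    "adjust_by",
    "adjust_bh",
    "go_module_prune",
    "Signature",
    "build_signature",
    "overlap_significance",
    "precision_recall",
]


def _group_columns(
    profile: MechanismProfile, annotation: SampleAnnotation, group_of_interest: str | None
) -> tuple[str, str, pd.Series]:
    groups = annotation.groups().reindex(profile.sample_ids)
    if groups.isna().any():
        missing = groups.index[groups.isna()].tolist()
        raise ValueError(f"samples missing from annotation: {missing[:5]}")
    labels = groups.unique().tolist()
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    if group_of_interest is None:
        group_of_interest = labels[0]
    other = [g for g in labels if g != group_of_interest][0]
    return group_of_interest, other, groups


def _z_unpaired(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Row-wise unpaired z: (mean1-mean2)/sqrt(s1^2/n1 + s2^2/n2)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (m1 - m2) / np.where(se > 0, se, 1.0), 0.0)
    return z


def _z_paired(d: np.ndarray) -> np.ndarray:
    """Row-wise one-sample z on per-pair differences."""
    n = d.shape[1]
    if n < 2:
        raise ValueError("need at least two pairs")
    m = d.mean(axis=1)
    s = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, m / np.where(s > 0, s, 1.0) * np.sqrt(n), 0.0)
    return z


def _paired_differences(
    profile: MechanismProfile, annotation: SampleAnnotation, goi: str, other: str
) -> np.ndarray:
    tab = annotation.table
    if "pair_id" not in tab.columns:
        raise ValueError("paired test requires a pair_id annotation column")
    tab = tab.set_index("sample_id").reindex(profile.sample_ids)
    pairs = {}
    for sid, row in tab.iterrows():
        pairs.setdefault(row["pair_id"], {})[row["group"]] = sid
    cols_a, cols_b = [], []
    for pid, members in sorted(pairs.items()):
        if set(members) != {goi, other}:
            raise ValueError(f"pair {pid!r} does not contain one sample of each group")
        cols_a.append(members[goi])
        cols_b.append(members[other])
    x = profile.scores
    return x[cols_a].to_numpy() - x[cols_b].to_numpy()


def ztest_mechanisms(
    profile: MechanismProfile,
    annotation: SampleAnnotation,
    group_of_interest: str | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-mechanism Z-test of scores between the two phenotype groups.

    Returns a frame indexed by mechanism with ``z``, ``direction`` (up =
    higher in the group of interest) and two-sided normal ``p``.
    Mechanisms with zero variance get z = 0, p = 1 with a warning.
    """
    goi, other, groups = _group_columns(profile, annotation, group_of_interest)
    if paired:
        z = _z_paired(_paired_differences(profile, annotation, goi, other))
    else:
        x = profile.scores
        z = _z_unpaired(
            x.loc[:, groups == goi].to_numpy(), x.loc[:, groups == other].to_numpy()
        )
    if np.any(z == 0):
        n0 = int(np.sum(z == 0))
        logger.warning("%d mechanisms with zero z (possibly zero variance)", n0)
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "z": z,
            "direction": np.where(z >= 0, "up", "down"),
            "p": p,
        },
        index=profile.mechanism_ids,
    )


def permutation_null(
    profile: MechanismProfile,
    annotation: SampleAnnotation,
    n_perm: int = 1000,
    seed: int | None = None,
    group_of_interest: str | None = None,
    paired: bool = False,
    pooled: bool = False,
    exhaustive: bool = False,
) -> pd.Series:
    """Empirical p per mechanism from joint phenotype-label permutation.

    Each permutation reassigns group labels (independent within-pair
    sign flips when paired) and recomputes all mechanism z statistics at
    once.  Empirical p uses the pseudo-count convention
    ``(1 + #{|z_null| >= |z_obs|}) / (n_perm + 1)``, so p is never zero.
    With ``pooled=True`` the null statistics of all mechanisms form one
    shared null distribution.  With ``exhaustive=True`` all distinct
    label assignments (group splits, or sign patterns when paired) are
    enumerated instead of sampled and the empirical p is the exact
    fraction ``#{|z_null| >= |z_obs|} / n_splits`` (the observed
    assignment is one of the splits, so p is never zero).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not exhaustive and n_perm < 100:
        logger.warning("n_perm=%d gives a coarse empirical-p resolution", n_perm)
    rng = np.random.default_rng(seed)
    goi, other, groups = _group_columns(profile, annotation, group_of_interest)

    if paired:
        d_obs = _paired_differences(profile, annotation, goi, other)
        z_obs = np.abs(_z_paired(d_obs))
        n_pairs = d_obs.shape[1]
        if exhaustive:
            from itertools import product

            patterns = list(product([-1.0, 1.0], repeat=n_pairs))
            null = np.empty((len(patterns), len(z_obs)))
            for b, signs in enumerate(patterns):
                null[b] = np.abs(_z_paired(d_obs * np.asarray(signs)))
        else:
            null = np.empty((n_perm, len(z_obs)))
            for b in range(n_perm):
                signs = rng.choice([-1.0, 1.0], size=n_pairs)
                null[b] = np.abs(_z_paired(d_obs * signs))
    else:
        x = profile.scores.to_numpy()
        lab = (groups == goi).to_numpy()
        z_obs = np.abs(_z_unpaired(x[:, lab], x[:, ~lab]))
        if exhaustive:
            from itertools import combinations

            n, k = len(lab), int(lab.sum())
            splits = list(combinations(range(n), k))
            null = np.empty((len(splits), len(z_obs)))
            for b, idx in enumerate(splits):
                perm = np.zeros(n, dtype=bool)
                perm[list(idx)] = True
                null[b] = np.abs(_z_unpaired(x[:, perm], x[:, ~perm]))
        else:
            null = np.empty((n_perm, len(z_obs)))
            for b in range(n_perm):
                perm = rng.permutation(lab)
                null[b] = np.abs(_z_unpaired(x[:, perm], x[:, ~perm]))

    tol = 1e-12  # |z| recomputed on the observed split must count as >=
    if exhaustive:
        p_emp = (null >= z_obs[None, :] - tol).sum(axis=0) / null.shape[0]
    elif pooled:
        flat = np.sort(null.ravel())
        exceed = len(flat) - np.searchsorted(flat, z_obs, side="left")
        p_emp = (1 + exceed) / (null.size + 1)
    else:
        p_emp = (1 + (null >= z_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    return pd.Series(p_emp, index=profile.mechanism_ids, name="p_empirical")


def adjust_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_by(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    Equals BH multiplied by ``c(m) = sum_{i=1}^{m} 1/i``, capped at 1 and
    monotone in the sorted order; valid under arbitrary dependence.
    """
    p = np.asarray(list(pvals), float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def test_mechanisms(
    profile: MechanismProfile,
    annotation: SampleAnnotation,
    group_of_interest: str | None = None,
    paired: bool = False,
    n_perm: int = 1000,
    seed: int | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full per-mechanism deregulation test.

    Combines the analytic Z-test, the joint label-permutation empirical
    p, and BY adjustment of the analytic p; ``retained`` flags q <= fdr.
    """
    res = ztest_mechanisms(profile, annotation, group_of_interest, paired)
    res["p_empirical"] = permutation_null(
        profile, annotation, n_perm=n_perm, seed=seed,
        group_of_interest=group_of_interest, paired=paired,
    )
    res["q"] = adjust_by(res["p"])
    res["retained"] = res["q"] <= fdr
    return res


def go_module_prune(
    qvalues: Mapping[str, float], dag: nx.DiGraph
) -> list[str]:
    """Keep one representative term per connected region of significant terms.

    The significant terms (the keys of ``qvalues``) are partitioned into
    connected components of the ontology graph's undirected skeleton
    restricted to those terms; each component contributes its
    smallest-q term (ties broken by term id).  Terms absent from the
    graph are kept as their own singleton region with a warning.
    """
    terms = list(qvalues)
    if not terms:
        return []
    in_dag = [t for t in terms if t in dag]
    orphans = [t for t in terms if t not in dag]
    if orphans:
        logger.warning("%d significant terms absent from the DAG; kept as-is", len(orphans))
    sub = dag.to_undirected().subgraph(in_dag)
    reps = []
    for comp in nx.connected_components(sub):
        reps.append(min(comp, key=lambda t: (qvalues[t], t)))
    reps.extend(orphans)
    return sorted(reps)


@dataclass
class Signature:
    """Directions of the significantly deregulated mechanisms of one dataset."""

    dataset_id: str
    directions: dict[str, str]  # mechanism id -> "up" | "down"

    @property
    def mechanisms(self) -> set[str]:
        return set(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"mechanism": list(self.directions), "direction": list(self.directions.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, dataset_id: str = "") -> "Signature":
        df = pd.read_csv(path, sep="\t")
        return cls(dataset_id, dict(zip(df["mechanism"], df["direction"])))


def build_signature(
    results: pd.DataFrame,
    fdr: float = 0.05,
    dag: nx.DiGraph | None = None,
    dataset_id: str = "",
) -> Signature:
    """Mechanisms with q <= fdr (representative-pruned when a DAG is given)."""
    sig = results[results["q"] <= fdr]
    ids = list(sig.index)
    if dag is not None and ids:
        ids = go_module_prune(dict(zip(sig.index, sig["q"])), dag)
    return Signature(dataset_id, {m: results.loc[m, "direction"] for m in ids})


def overlap_significance(
    signatures: Sequence[Signature],
    universes: Sequence[Sequence[str]],
    n_resample: int = 1000,
    seed: int | None = None,
) -> dict:
    """k-way signature overlap and its resampling significance.

    The overlap fraction is |intersection| / |union| over the mechanism
    sets.  For the null, a term set of the same size is drawn without
    replacement from each dataset's tested universe ``n_resample``
    times; the empirical p is the pseudo-counted proportion of draws
    whose k-way intersection is at least the observed one.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two signatures")
    if len(universes) != len(signatures):
        raise ValueError("one universe per signature required")
    sets = [s.mechanisms for s in signatures]
    for s, u in zip(sets, universes):
        if not s <= set(u):
            raise ValueError("signature contains terms outside its universe")
    inter = set.intersection(*sets)
    union = set.union(*sets)
    frac = len(inter) / len(union) if union else 0.0

    rng = np.random.default_rng(seed)
    universes = [np.asarray(list(u)) for u in universes]
    sizes = [len(s) for s in sets]
    b = 0
    for _ in range(n_resample):
        draws = [
            set(rng.choice(u, size=k, replace=False)) for u, k in zip(universes, sizes)
        ]
        if len(set.intersection(*draws)) >= len(inter):
            b += 1
    return {
        "intersection": sorted(inter),
        "intersection_size": len(inter),
        "union_size": len(union),
        "overlap_fraction": frac,
        "p_empirical": (1 + b) / (n_resample + 1),
        "n_resample": n_resample,
    }


def precision_recall(predicted: Sequence[str], gold: Sequence[str]) -> pd.DataFrame:
    """Precision/recall at each prefix of a ranked term list.

    A flat (unranked) list yields its single final point.  An empty
    prediction yields one row with recall 0 and precision NaN.
    """
    gold_set = set(gold)
    if not gold_set:
        raise ValueError("gold-standard term set is empty")
    if len(set(predicted)) != len(predicted):
        raise ValueError("predicted list contains duplicates")
    if not len(predicted):
        return pd.DataFrame({"rank": [0], "precision": [np.nan], "recall": [0.0]})
    hits = np.cumsum([t in gold_set for t in predicted])
    ks = np.arange(1, len(predicted) + 1)
    return pd.DataFrame(
        {
            "rank": ks,
            "term": list(predicted),
            "precision": hits / ks,
            "recall": hits / len(gold_set),
        }
    )
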