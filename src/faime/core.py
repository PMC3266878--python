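"""Single-sample rank-weighted mechanism scoring.

The score of a gene set in one sample is computed entirely within that
sample, in four steps:

1. All measured genes G are sorted by decreasing expression; gene g gets
   rank ``r`` (1 = highest) and the exponentially decreasing weight
   ``w(r) = exp(-decay * r / |G|)``.
2. Each gene's expression value is multiplied by its rank weight
   (prioritising relatively highly expressed genes).
3. The normalized centroid NC of a gene subset is the arithmetic mean of
   its members' weighted values; the score of a set is
   ``F = NC(set) - NC(complement)``, the complement being all measured
   genes outside the set.
4. Stacking F over all retained mechanisms yields the per-sample
   mechanism profile.

Because ranks are computed within a sample, profiles are sample
independent: adding or removing other samples never changes a sample's
scores, and any strictly increasing transform of a sample's expression
leaves its ranks and weights unchanged.

Mean-G and Median-G comparator scores (plain per-set mean/median of raw
log2 expression, no weighting, no complement) are provided for
benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "rank_weight",
    "rank_and_weight",
    "weighted_expression",
    "normalized_centroid",
    "faime_score",
    "faime_profile",
    "mean_g",
    "median_g",
    "comparator_profile",
    "MechanismProfile",
    "ScoreRecord",
]

DEFAULT_DECAY = 1.0

TieMethod = Literal["ordinal", "average"]


def rank_weight(ranks: np.ndarray, n_genes: int, decay: float = DEFAULT_DECAY) -> np.ndarray:
    """Exponentially decreasing weight of a rank: ``exp(-decay * r / n)``.

    ``decay`` controls how steeply weight falls off across the ranked
    list: with the default of 1 the weight drops by one e-fold from the
    top to the bottom of the list.  This function is the single point of
    substitution for alternative weight schemes.
    """
    if decay < 0:
        raise ValueError("decay must be non-negative")
    return np.exp(-decay * np.asarray(ranks, float) / n_genes)


def _ranks(values: np.ndarray, tie_method: TieMethod) -> np.ndarray:
    """Descending ranks, 1 = highest expression.

    ``ordinal`` breaks ties by position in the gene-id-sorted input
    (deterministic); ``average`` assigns mid-ranks to ties.
    """
    if tie_method == "ordinal":
        order = np.lexsort((np.arange(len(values)), -values))
        ranks = np.empty(len(values), dtype=float)
        ranks[order] = np.arange(1, len(values) + 1)
        return ranks
    if tie_method == "average":
        return rankdata(-values, method="average")
    raise ValueError(f"unknown tie method {tie_method!r}")


def rank_and_weight(
    sample_expression: pd.Series,
    decay: float = DEFAULT_DECAY,
    tie_method: TieMethod = "ordinal",
) -> pd.DataFrame:
    """Rank one sample's genes and attach their exponential weights.

    Missing (NaN) genes are excluded; the remaining genes define this
    sample's universe and its size |G|.  Returns a frame indexed by gene
    with columns ``rank`` and ``weight``.
    """
    expr = sample_expression.dropna().sort_index()
    if len(expr) < 2:
        raise ValueError("need at least two measured genes to rank")
    ranks = _ranks(expr.to_numpy(float), tie_method)
    weights = rank_weight(ranks, len(expr), decay)
    return pd.DataFrame({"rank": ranks, "weight": weights}, index=expr.index)


def weighted_expression(
    sample_expression: pd.Series,
    weighting: pd.DataFrame,
    weight_only: bool = False,
) -> pd.Series:
    """Element-wise product of expression and rank weight.

    With ``weight_only=True`` the raw values are ignored and the weights
    themselves are returned (a pure rank-based variant).
    """
    expr = sample_expression.dropna().sort_index()
    if not expr.index.equals(weighting.index):
        raise ValueError("weighting was not computed from this sample")
    if weight_only:
        return weighting["weight"].copy()
    return expr * weighting["weight"]


def normalized_centroid(weighted_values: pd.Series, gene_subset) -> float:
    """Cardinality-normalized sum (i.e. mean) of weighted values over a subset."""
    subset = list(gene_subset)
    if not subset:
        raise ValueError("gene subset is empty")
    missing = set(subset) - set(weighted_values.index)
    if missing:
        raise KeyError(f"genes outside the universe: {sorted(missing)[:5]}")
    return float(weighted_values.loc[subset].mean())


@dataclass(frozen=True)
class ScoreRecord:
    mechanism_id: str
    sample_id: str
    score: float
    nc_set: float
    nc_complement: float


def faime_score(
    sample_expression: pd.Series,
    geneset: GeneSet,
    decay: float = DEFAULT_DECAY,
    tie_method: TieMethod = "ordinal",
    weight_only: bool = False,
    sample_id: str = "",
) -> ScoreRecord:
    """Score one gene set in one sample: NC(set) - NC(complement)."""
    weighting = rank_and_weight(sample_expression, decay, tie_method)
    wv = weighted_expression(sample_expression, weighting, weight_only)
    universe = set(wv.index)
    members = geneset.members & universe
    complement = universe - geneset.members
    if not members:
        raise ValueError(f"gene set {geneset.id!r} shares no genes with the universe")
    if not complement:
        raise ValueError(f"gene set {geneset.id!r} covers the whole universe")
    nc_set = normalized_centroid(wv, members)
    nc_comp = normalized_centroid(wv, complement)
    return ScoreRecord(geneset.id, sample_id, nc_set - nc_comp, nc_set, nc_comp)


@dataclass
class MechanismProfile:
    """Mechanism scores, mechanisms x samples, plus scoring provenance."""

    scores: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def mechanism_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def subset(self, mechanism_ids) -> "MechanismProfile":
        ids = [m for m in mechanism_ids if m in self.scores.index]
        missing = set(mechanism_ids) - set(ids)
        if missing:
            raise KeyError(f"mechanisms absent from profile: {sorted(missing)[:5]}")
        return MechanismProfile(self.scores.loc[ids].copy(), dict(self.metadata))

    def write_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="mechanism")

    @classmethod
    def read_tsv(cls, path, metadata: dict | None = None) -> "MechanismProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df, metadata or {})


def faime_profile(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    decay: float = DEFAULT_DECAY,
    tie_method: TieMethod = "ordinal",
    weight_only: bool = False,
) -> MechanismProfile:
    """Score every mechanism in every sample.

    Each sample is processed independently; a sample's column depends
    only on that sample's expression vector.  Genes missing in a sample
    are excluded from that sample's universe, so |G| is per-sample.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    vals = matrix.values.sort_index()
    genes = vals.index
    gene_pos = {g: i for i, g in enumerate(genes)}

    # mechanisms x genes membership (bool); scoring uses members within the matrix
    membership = np.zeros((len(collection), len(genes)), dtype=bool)
    for i, s in enumerate(collection):
        idx = [gene_pos[g] for g in s.members if g in gene_pos]
        if not idx:
            raise ValueError(f"gene set {s.id!r} shares no genes with the matrix")
        membership[i, idx] = True

    arr = vals.to_numpy(float)
    valid = ~np.isnan(arr)
    wv = np.zeros_like(arr)
    for j in range(arr.shape[1]):
        col_valid = valid[:, j]
        n = int(col_valid.sum())
        if n < 2:
            raise ValueError(f"sample {vals.columns[j]!r} has <2 measured genes")
        v = arr[col_valid, j]
        ranks = _ranks(v, tie_method)
        w = rank_weight(ranks, n, decay)
        wv[col_valid, j] = w if weight_only else w * v

    set_sum = membership.astype(float) @ wv
    set_n = membership.astype(float) @ valid.astype(float)
    tot_sum = wv.sum(axis=0)
    tot_n = valid.sum(axis=0).astype(float)
    comp_n = tot_n - set_n
    if (set_n == 0).any() or (comp_n == 0).any():
        raise ValueError("a gene set is empty or covers the whole universe in some sample")
    scores = set_sum / set_n - (tot_sum - set_sum) / comp_n

    df = pd.DataFrame(scores, index=collection.ids, columns=vals.columns)
    meta = {
        "decay": decay,
        "tie_method": tie_method,
        "weight_only": weight_only,
        "n_mechanisms": len(collection),
        "n_genes": len(genes),
    }
    return MechanismProfile(df, meta)


def mean_g(sample_expression: pd.Series, geneset: GeneSet) -> float:
    """Comparator score: plain mean of raw log2 expression over members."""
    members = geneset.members & set(sample_expression.dropna().index)
    if not members:
        raise ValueError(f"gene set {geneset.id!r} has no measured members")
    return float(sample_expression.loc[sorted(members)].mean())


def median_g(sample_expression: pd.Series, geneset: GeneSet) -> float:
    """Comparator score: plain median of raw log2 expression over members."""
    members = geneset.members & set(sample_expression.dropna().index)
    if not members:
        raise ValueError(f"gene set {geneset.id!r} has no measured members")
    return float(sample_expression.loc[sorted(members)].median())


def comparator_profile(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    statistic: Literal["mean", "median"] = "mean",
) -> MechanismProfile:
    """Mean-G / Median-G profile over all mechanisms and samples."""
    fn = mean_g if statistic == "mean" else median_g
    rows = {
        s.id: [fn(matrix.values[c], s) for c in matrix.values.columns]
        for s in collection
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.values.columns)
    return MechanismProfile(df.loc[collection.ids], {"statistic": statistic})
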