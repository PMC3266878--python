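"""Readers, writers and pre-scoring filters.

External formats are deliberately plain text: tab-separated expression
matrices (genes x samples, header row of sample ids, first column gene
symbols, empty cells = missing), GMT v1 gene-set files, a two-column
child->parent edge list for an ontology DAG, and a TSV sample-annotation
table with the columns ``sample_id, group, pair_id, patient_id, time,
event`` (all but the first two optional).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "SampleAnnotation",
    "FilterReport",
    "read_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "filter_probes_iqr",
    "filter_genesets",
    "read_dag",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples; NaN marks a missing measurement."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression body must be numeric")
        with np.errstate(invalid="ignore"):
            if np.isinf(arr).any():
                raise FormatError("expression values must be finite or missing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Parse a genes-x-samples TSV; non-numeric body cells are reported
    with their row/column coordinates."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    body = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    nonempty = df.notna() & df.apply(lambda c: c.astype(str).str.strip() != "")
    bad = body.isna() & nonempty
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    body = body.astype(float)
    body.index.name = None
    return ExpressionMatrix(body)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (mechanism): a KEGG pathway, GO term or custom set."""

    id: str
    name: str = ""
    namespace: str = "custom"
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """An ordered collection of gene sets with unique ids."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets = list(sets)
        ids = [s.id for s in self.sets]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene-set ids in collection: {dups[:5]}")
        self._by_id = {s.id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT v1 file: ``id<TAB>description<TAB>gene...`` per line.

    Within-line duplicate genes are deduplicated with a warning; a line
    with fewer than three fields or a repeated set id is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 tab-separated fields")
            set_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if set_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene-set id {set_id!r}")
            seen.add(set_id)
            if len(set(genes)) != len(genes):
                logger.warning("gene set %s: duplicate members deduplicated", set_id)
            sets.append(GeneSet(id=set_id, name=desc, members=frozenset(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.id, s.name, *sorted(s.members)]) + "\n")


@dataclass
class SampleAnnotation:
    """Phenotype table: group label plus optional pairing, patient id and
    right-censored survival columns (time in months, event 0/1)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group")
    OPTIONAL = ("pair_id", "patient_id", "time", "event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"annotation missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in annotation")
        has_time = "time" in self.table.columns and self.table["time"].notna()
        has_event = "event" in self.table.columns and self.table["event"].notna()
        if isinstance(has_time, pd.Series) or isinstance(has_event, pd.Series):
            t = has_time if isinstance(has_time, pd.Series) else pd.Series(False, index=self.table.index)
            e = has_event if isinstance(has_event, pd.Series) else pd.Series(False, index=self.table.index)
            if (t ^ e).any():
                raise FormatError("survival time and event must be given together")
        if "time" in self.table.columns:
            t = pd.to_numeric(self.table["time"], errors="raise")
            if (t.dropna() < 0).any():
                raise FormatError("survival times must be non-negative")

    @classmethod
    def read_tsv(cls, path) -> "SampleAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]


def read_probe_map(path) -> dict[str, str]:
    """Two-column TSV probe_id -> gene symbol; many probes per gene allowed."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    if df["probe"].duplicated().any():
        raise FormatError("a probe maps to more than one gene")
    return dict(zip(df["probe"], df["gene"]))


@dataclass
class FilterReport:
    n_probes_in: int
    n_genes_out: int
    n_dropped_negative_mean: int
    n_dropped_missing: int


def _row_iqr(values: np.ndarray) -> np.ndarray:
    """Per-row IQR (linear-interpolation quantiles), ignoring NaNs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q75 = np.nanpercentile(values, 75, axis=1)
        q25 = np.nanpercentile(values, 25, axis=1)
    return q75 - q25


def filter_probes_iqr(
    matrix: ExpressionMatrix,
    probe_map: Mapping[str, str],
    max_missing_frac: float = 0.5,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Collapse a probe-level matrix to gene level.

    For each gene the probe with the largest inter-quartile range across
    samples is retained (ties broken by lexicographically smallest probe
    id); genes whose winning probe has a negative mean log2 expression
    across all samples are removed, as are rows with more than
    ``max_missing_frac`` missing values.
    """
    unmapped = [p for p in matrix.values.index if p not in probe_map]
    if unmapped:
        raise KeyError(f"probes absent from map: {unmapped[:10]}")
    vals = matrix.values
    iqr = pd.Series(_row_iqr(vals.to_numpy(float)), index=vals.index)
    genes = pd.Series({p: probe_map[p] for p in vals.index})

    choice = (
        pd.DataFrame({"gene": genes, "iqr": iqr, "probe": vals.index})
        .sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
        .groupby("gene", sort=True)
        .head(1)
    )
    picked = vals.loc[choice["probe"]]
    picked.index = choice["gene"].to_numpy()

    n_miss = picked.isna().mean(axis=1)
    too_missing = n_miss > max_missing_frac
    if too_missing.any():
        logger.warning(
            "%d gene rows dropped: >%d%% missing",
            int(too_missing.sum()),
            int(max_missing_frac * 100),
        )
    picked = picked.loc[~too_missing]

    mean = picked.mean(axis=1, skipna=True)
    neg = mean < 0
    out = picked.loc[~neg].sort_index()
    report = FilterReport(
        n_probes_in=len(vals),
        n_genes_out=len(out),
        n_dropped_negative_mean=int(neg.sum()),
        n_dropped_missing=int(too_missing.sum()),
    )
    return ExpressionMatrix(out), report


def filter_genesets(
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    min_genes: int = 4,
) -> GeneSetCollection:
    """Intersect each set with the measured gene universe and drop sets
    with fewer than ``min_genes`` measurable members.

    The default of 4 keeps sets with strictly more than 3 measured genes.
    Downstream scoring uses the intersected membership.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    universe = set(matrix.gene_ids)
    kept = []
    for s in collection:
        measurable = s.members & universe
        if len(measurable) >= min_genes:
            kept.append(GeneSet(s.id, s.name, s.namespace, frozenset(measurable)))
    if not kept:
        raise ValueError(
            "no gene set retains >= "
            f"{min_genes} measurable genes; check that gene identifiers in the "
            "collection and the matrix agree"
        )
    return GeneSetCollection(kept)


def read_dag(path) -> nx.DiGraph:
    """Read a two-column child->parent edge list into a directed acyclic graph."""
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
    g = nx.DiGraph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise FormatError(f"edge list contains a cycle: {cycle}")
    return g
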