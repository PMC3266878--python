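import numpy as np
import pandas as pd
import pytest

from faime.io import ExpressionMatrix, GeneSet, GeneSetCollection, SampleAnnotation


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """8 genes x 4 samples, deterministic values, no missingness."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{j}" for j in range(4)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(7, 1, size=(8, 4)), index=genes, columns=samples)
    )


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("M1", "top", "custom", frozenset({"g0", "g1", "g2"})),
            GeneSet("M2", "mixed", "custom", frozenset({"g3", "g4", "g5", "g6"})),
            GeneSet("M3", "pairish", "custom", frozenset({"g1", "g7"})),
        ]
    )


@pytest.fixture
def two_group_annotation() -> SampleAnnotation:
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["s0", "s1", "s2", "s3"],
                "group": ["tumor", "tumor", "control", "control"],
            }
        )
    )


def brute_force_profile(matrix, collection, decay=1.0, weight_only=False):
    """Independent mechanism-score implementation using plain Python loops.

    Sorts each sample's measured genes by decreasing value (ties by gene
    id), assigns rank r = 1.. and weight exp(-decay*r/|G|), multiplies
    weight by value, and scores each set as mean-over-members minus
    mean-over-complement.  Shares no code with the library path.
    """
    import math

    scores = {}
    for sample in matrix.values.columns:
        col = matrix.values[sample].dropna()
        items = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        n = len(items)
        wv = {}
        for r, (g, v) in enumerate(items, start=1):
            w = math.exp(-decay * r / n)
            wv[g] = w if weight_only else w * v
        for s in collection:
            inside = [wv[g] for g in wv if g in s.members]
            outside = [wv[g] for g in wv if g not in s.members]
            f = sum(inside) / len(inside) - sum(outside) / len(outside)
            scores.setdefault(s.id, {})[sample] = f
    return pd.DataFrame(scores).T.loc[collection.ids, matrix.values.columns]
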