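"""Prognostic analysis of mechanism profiles.

Patients are stratified in an unsupervised way by k-medoids (CLARA-style
partitioning; solved exactly at desk scale) on their mechanism-score
vectors, and the resulting groups are compared with Kaplan-Meier curves
and the log-rank test.  Per-mechanism prognostic power is assessed with
a univariate Cox proportional-hazards fit of recurrence-free survival on
the mechanism score, combined across independent cohorts by a signed
Stouffer Z meta-analysis with Bonferroni control.  As a cross-check, a
mechanism's score can be compared against the first principal component
of its member genes' expression (Spearman correlation plus a Cox fit on
PC1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm, spearmanr
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .core import MechanismProfile
from .evaluation import pam
from .io import ExpressionMatrix, GeneSetCollection, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalTable",
    "prepare_patient_profiles",
    "clara_partition",
    "km_logrank",
    "cox_per_mechanism",
    "stouffer_meta",
    "p_to_z",
    "bonferroni",
    "meta_analyze",
    "pca_pc1_check",
]


@dataclass
class SurvivalTable:
    """One row per patient: time (months), event (1 = event, 0 = censored),
    optional group assignment from partitioning."""

    table: pd.DataFrame  # columns: patient_id, time, event[, group]

    def __post_init__(self) -> None:
        for col in ("patient_id", "time", "event"):
            if col not in self.table.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if self.table["patient_id"].duplicated().any():
            raise ValueError("duplicate patients; average duplicate samples first")
        t = self.table["time"].to_numpy(float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("times must be finite and non-negative")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")

    @classmethod
    def from_annotation(cls, annotation: SampleAnnotation) -> "SurvivalTable":
        tab = annotation.table
        key = "patient_id" if "patient_id" in tab.columns else "sample_id"
        rows = (
            tab.dropna(subset=["time", "event"])
            .groupby(key, sort=True)
            .agg(time=("time", "first"), event=("event", "first"))
            .reset_index()
            .rename(columns={key: "patient_id"})
        )
        return cls(rows)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SurvivalTable":
        return cls(pd.read_csv(path, sep="\t"))


def prepare_patient_profiles(
    profile: MechanismProfile, annotation: SampleAnnotation
) -> MechanismProfile:
    """Average duplicate samples of a patient mechanism-wise.

    Avoids duplicate dependent measures per patient in partitioning and
    Cox fits; patients with a single sample pass through unchanged.
    """
    tab = annotation.table
    key = "patient_id" if "patient_id" in tab.columns else "sample_id"
    pat = tab.set_index("sample_id")[key].reindex(profile.sample_ids)
    if pat.isna().any():
        missing = pat.index[pat.isna()].tolist()
        logger.warning("samples without a patient id excluded: %s", missing[:5])
    groups: dict[str, list[str]] = {}
    for sid, pid in pat.dropna().items():
        groups.setdefault(pid, []).append(sid)
    cols = {pid: profile.scores[sids].mean(axis=1) for pid, sids in sorted(groups.items())}
    df = pd.DataFrame(cols)
    return MechanismProfile(df, {**profile.metadata, "patient_averaged": True})


def clara_partition(
    patient_profiles: MechanismProfile, k: int = 2, seed: int | None = None
) -> pd.Series:
    """Unsupervised k-medoids partition of patients (k = 2 or 3 typical).

    At cohort sizes of interest the exact PAM objective is optimised
    (CLARA's subsampling is an approximation to PAM that large-n forces;
    it is unnecessary here).  Returns patient id -> group label 0..k-1.
    """
    x = patient_profiles.scores.to_numpy().T
    if x.shape[0] < k:
        raise ValueError("fewer patients than groups")
    d = squareform(pdist(x, metric="euclidean"))
    labels, _ = pam(d, k=k, seed=seed)
    return pd.Series(labels, index=patient_profiles.sample_ids, name="group")


def km_logrank(table: SurvivalTable) -> dict:
    """Log-rank test across groups plus serialized Kaplan-Meier curves.

    Returns the chi-square statistic, its p-value and a tidy frame of
    per-group survival step functions (time, survival, at-risk).
    """
    tab = table.table
    if "group" not in tab.columns:
        raise ValueError("survival table has no group assignment")
    counts = tab["group"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if tab["event"].sum() == 0:
        raise ValueError("no events in the pooled data")
    res = multivariate_logrank_test(tab["time"], tab["group"], tab["event"])
    curves = []
    for g, sub in tab.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        sf = kmf.survival_function_
        ev = kmf.event_table
        curves.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": sf.index,
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "at_risk": ev["at_risk"].reindex(sf.index).to_numpy(),
                }
            )
        )
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "curves": pd.concat(curves, ignore_index=True),
    }


def cox_per_mechanism(
    patient_profiles: MechanismProfile,
    table: SurvivalTable,
    collection: GeneSetCollection | None = None,
    matrix: ExpressionMatrix | None = None,
    min_genes: int = 4,
) -> pd.DataFrame:
    """Univariate Cox PH fit per mechanism (score as the sole covariate).

    When a gene-set collection and expression matrix are supplied,
    mechanisms with fewer than ``min_genes`` measurable member genes are
    excluded before fitting.  Efron tie handling.  Non-converging fits
    are flagged (``converged=False``), never silently dropped.  Returns
    a frame with coefficient, z, p and direction (sign of the hazard
    association).
    """
    mechs = patient_profiles.mechanism_ids
    if collection is not None:
        universe = set(matrix.gene_ids) if matrix is not None else None
        keep = []
        for m in mechs:
            if m not in collection:
                continue
            members = collection[m].members
            measurable = members & universe if universe is not None else members
            if len(measurable) >= min_genes:
                keep.append(m)
        mechs = keep
    tab = table.table.set_index("patient_id")
    patients = [p for p in patient_profiles.sample_ids if p in tab.index]
    if not patients:
        raise ValueError("no overlap between profile patients and survival table")
    if tab.loc[patients, "event"].sum() == 0:
        raise ValueError("no events among profiled patients")
    rows = []
    for m in mechs:
        df = pd.DataFrame(
            {
                "time": tab.loc[patients, "time"].to_numpy(float),
                "event": tab.loc[patients, "event"].to_numpy(int),
                "score": patient_profiles.scores.loc[m, patients].to_numpy(float),
            }
        )
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
            coef = float(cph.params_["score"])
            se = float(cph.standard_errors_["score"])
            z = coef / se if se > 0 else 0.0
            rows.append((m, coef, z, 2 * norm.sf(abs(z)), np.sign(coef), True))
        except Exception as exc:  # convergence failure on a degenerate covariate
            logger.warning("Cox fit failed for %s: %s", m, exc)
            rows.append((m, np.nan, np.nan, np.nan, 0.0, False))
    return pd.DataFrame(
        rows, columns=["mechanism", "coef", "z", "p", "direction", "converged"]
    ).set_index("mechanism")


def p_to_z(p: float, direction: float, one_sided: bool = False) -> float:
    """Signed normal quantile of a study p-value.

    ``direction`` (+1/-1) is the sign of the association (positive =
    higher score, higher hazard).  Two-sided p contributes |z| =
    Phi^-1(1 - p/2); one-sided p contributes Phi^-1(1 - p).  A zero p is
    clamped to the smallest representable positive value with a warning.
    """
    if p <= 0:
        logger.warning("p = 0 clamped to float tiny")
        p = np.finfo(float).tiny
    q = p if one_sided else p / 2
    return float(np.sign(direction) * norm.isf(q))


def stouffer_meta(z_scores) -> tuple[float, float]:
    """Signed Stouffer combination: z_meta = sum(z_i)/sqrt(k).

    Returns (z_meta, two-sided p).  Same-direction studies reinforce;
    opposite directions cancel.
    """
    z = np.asarray(list(z_scores), float)
    if z.size == 0:
        raise ValueError("no studies to combine")
    z_meta = z.sum() / np.sqrt(z.size)
    return float(z_meta), float(2 * norm.sf(abs(z_meta)))


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, m * p)."""
    return np.minimum(1.0, m * np.asarray(p, float))


def meta_analyze(per_dataset: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-mechanism Cox results from several cohorts.

    Mechanisms present (and converged) in every cohort are combined
    with the signed Stouffer Z (sign = hazard direction, applied per
    cohort before summing); the joint two-sided p is Bonferroni-adjusted
    for the number of combined mechanisms.
    """
    if not per_dataset:
        raise ValueError("no cohorts supplied")
    common = set(per_dataset[0].index)
    for df in per_dataset[1:]:
        common &= set(df.index)
    common = sorted(
        m for m in common if all(bool(df.loc[m, "converged"]) for df in per_dataset)
    )
    if not common:
        raise ValueError("no mechanism converged in every cohort")
    rows = []
    for m in common:
        zs = [float(df.loc[m, "z"]) for df in per_dataset]
        z_meta, p_meta = stouffer_meta(zs)
        rows.append((m, z_meta, p_meta))
    out = pd.DataFrame(rows, columns=["mechanism", "z_meta", "p_meta"]).set_index("mechanism")
    out["p_bonferroni"] = bonferroni(out["p_meta"], len(out))
    return out.sort_values("p_bonferroni")


def pca_pc1_check(
    matrix: ExpressionMatrix,
    geneset_members,
    mechanism_scores: pd.Series,
    table: SurvivalTable | None = None,
) -> dict:
    """Cross-check a mechanism score against PC1 of its member genes.

    PC1 of the centered gene-level expression (patients as observations,
    the set's measurable genes as features), sign-oriented to correlate
    non-negatively with the set's mean expression; Spearman rho/p versus
    the mechanism scores, and optionally a univariate Cox fit on PC1.
    """
    genes = sorted(set(geneset_members) & set(matrix.gene_ids))
    if len(genes) < 2:
        raise ValueError("need at least two measurable member genes")
    patients = list(mechanism_scores.index)
    x = matrix.values.loc[genes, patients].to_numpy(float).T  # patients x genes
    if x.shape[0] < 3:
        raise ValueError("need at least three patients")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) == 0:
        raise ValueError("expression submatrix has rank 0")
    pca = PCA(n_components=1)
    pc1 = pca.fit_transform(x - x.mean(axis=0))[:, 0]
    mean_expr = x.mean(axis=1)
    if np.corrcoef(pc1, mean_expr)[0, 1] < 0:
        pc1 = -pc1
    rho, p = spearmanr(pc1, mechanism_scores.to_numpy(float))
    out = {
        "pc1": pd.Series(pc1, index=patients, name="pc1"),
        "explained_variance_ratio": float(pca.explained_variance_ratio_[0]),
        "spearman_rho": float(rho),
        "spearman_p": float(p),
    }
    if table is not None:
        tab = table.table.set_index("patient_id").loc[patients]
        df = pd.DataFrame(
            {"time": tab["time"].to_numpy(float), "event": tab["event"].to_numpy(int), "pc1": pc1}
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        out["cox_pc1_p"] = float(cph.summary.loc["pc1", "p"])
        out["cox_pc1_coef"] = float(cph.params_["pc1"])
    return out
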