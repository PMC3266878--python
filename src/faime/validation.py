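"""Property benchmarks on synthetic cohorts with known ground truth.

Each function sets up a fixed study condition (sample sizes, planted
effect sizes, mechanism counts), runs the package's own pipeline on
data from :mod:`faime.simulate`, and measures a quantity with a known
expected behaviour — an exact identity, an error rate, a recovery rate.
Where a benchmark checks the scoring arithmetic it compares against an
independently coded plain-loop reference kept in this module, never
against the vectorised path it is checking.

These functions power both the acceptance test suite and
``scripts/acceptance.py``; all randomness flows from the ``seed``
argument.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kstest, norm

from . import simulate
from .core import MechanismProfile, faime_profile, rank_and_weight, weighted_expression
from .differential import (
    adjust_bh,
    adjust_by,
    build_signature,
    permutation_null,
    ztest_mechanisms,
)
from .evaluation import CLUSTER_ALGORITHMS, cluster_samples, feature_permutation_p
from .io import ExpressionMatrix, GeneSet, GeneSetCollection, SampleAnnotation
from .survival import (
    SurvivalTable,
    clara_partition,
    cox_per_mechanism,
    km_logrank,
    meta_analyze,
    pca_pc1_check,
    prepare_patient_profiles,
)

__all__ = [
    "reference_profile",
    "score_oracle_benchmark",
    "conservation_benchmark",
    "rank_invariance_benchmark",
    "type1_error_benchmark",
    "power_benchmark",
    "by_adjustment_benchmark",
    "clustering_benchmark",
    "feature_permutation_benchmark",
    "permutation_exactness_benchmark",
    "survival_benchmark",
    "stouffer_benchmark",
    "logrank_oracle_benchmark",
    "pc1_concordance_benchmark",
]


# ---------------------------------------------------------------- references


def reference_profile(matrix, collection, decay=1.0):
    """Plain-loop mechanism scoring, kept independent of the library path.

    Sorts each sample's genes by decreasing value (ties by gene id),
    assigns rank r = 1..|G| and weight exp(-decay*r/|G|), multiplies by
    the value, and scores each set as mean over members minus mean over
    the complement.
    """
    out = {}
    for sample in matrix.values.columns:
        col = matrix.values[sample].dropna()
        items = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        n = len(items)
        wv = {}
        for r, (g, v) in enumerate(items, start=1):
            wv[g] = math.exp(-decay * r / n) * v
        for s in collection:
            inside = [wv[g] for g in wv if g in s.members]
            outside = [wv[g] for g in wv if g not in s.members]
            f = sum(inside) / len(inside) - sum(outside) / len(outside)
            out.setdefault(s.id, {})[sample] = f
    return pd.DataFrame(out).T.loc[collection.ids, matrix.values.columns]


def _random_small_instance(rng):
    n_genes = int(rng.integers(4, 13))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(int(rng.integers(2, 5)))]
    m = ExpressionMatrix(
        pd.DataFrame(
            rng.normal(6, 2, (n_genes, len(samples))), index=genes, columns=samples
        )
    )
    sets = [
        GeneSet(
            f"S{k}", "", "custom",
            frozenset(rng.choice(genes, int(rng.integers(1, n_genes)), replace=False)),
        )
        for k in range(int(rng.integers(1, 5)))
    ]
    return m, GeneSetCollection(sets)


# ------------------------------------------------------------- score algebra


def score_oracle_benchmark(seed: int, n_instances: int = 200) -> dict:
    """Max |library - reference| score over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m, coll = _random_small_instance(rng)
        decay = float(rng.uniform(0.2, 2.0))
        got = faime_profile(m, coll, decay=decay).scores.to_numpy()
        ref = reference_profile(m, coll, decay=decay).to_numpy()
        worst = max(worst, float(np.abs(got - ref).max()))
    return {"max_abs_error": worst, "n": n_instances}


def conservation_benchmark(seed: int, n_instances: int = 100) -> dict:
    """Max violation of |S| NC(S) + |G\\S| NC(G\\S) = total weighted sum."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_genes = int(rng.integers(4, 30))
        expr = pd.Series(
            rng.normal(6, 2, n_genes), index=[f"g{i}" for i in range(n_genes)]
        )
        wv = weighted_expression(expr, rank_and_weight(expr))
        total = float(wv.sum())
        k = int(rng.integers(1, n_genes))
        subset = list(rng.choice(expr.index, k, replace=False))
        comp = [g for g in expr.index if g not in set(subset)]
        lhs = float(wv.loc[subset].sum()) + float(wv.loc[comp].sum())
        worst = max(worst, abs(lhs - total))
    return {"max_abs_error": worst, "n": n_instances}


def rank_invariance_benchmark(seed: int, n_samples: int = 50) -> dict:
    """Max rank/weight discrepancy under strictly increasing transforms."""
    rng = np.random.default_rng(seed)
    transforms = [
        lambda v: np.exp(v),
        lambda v: 3.0 * v + 11.0,
        lambda v: v**3 + v,
    ]
    worst = 0.0
    for _ in range(n_samples):
        expr = pd.Series(
            rng.normal(0, 1, 30), index=[f"g{i}" for i in range(30)]
        )
        base = rank_and_weight(expr)
        for f in transforms:
            other = rank_and_weight(pd.Series(f(expr.to_numpy()), index=expr.index))
            worst = max(
                worst,
                float(np.abs(base.to_numpy() - other.to_numpy()).max()),
            )
    return {"max_abs_discrepancy": worst, "n": n_samples}


# ----------------------------------------------------- differential calling


def _null_config(seed):
    return simulate.SimulationConfig(seed=seed, planted={})


def type1_error_benchmark(
    seed: int, n_datasets: int = 200, n_ks_datasets: int = 2, n_perm: int = 500
) -> dict:
    """False-positive control on null cohorts (no planted effect).

    Returns the mean fraction of mechanisms reaching q <= 0.05 over
    ``n_datasets`` null datasets (20 tumors vs 20 controls, 200
    mechanisms) and the minimum KS uniformity p-value of the
    permutation empirical p across ``n_ks_datasets`` of them.
    """
    rng = np.random.default_rng(seed)
    fractions = []
    ks_ps = []
    for i in range(n_datasets):
        ds_seed = int(rng.integers(2**31 - 1))
        m, ann, coll, _ = simulate.generate_expression(_null_config(ds_seed))
        prof = faime_profile(m, coll)
        res = ztest_mechanisms(prof, ann, "tumor")
        q = adjust_by(res["p"])
        fractions.append(float(np.mean(q <= 0.05)))
        if i < n_ks_datasets:
            p_emp = permutation_null(
                prof, ann, n_perm=n_perm, seed=ds_seed, group_of_interest="tumor"
            )
            ks_ps.append(float(kstest(p_emp.to_numpy(), "uniform").pvalue))
    return {
        "mean_fraction_q_le_005": float(np.mean(fractions)),
        "min_ks_uniformity_p": float(min(ks_ps)),
        "n": n_datasets,
    }


def power_benchmark(seed: int, n_seeds: int = 100) -> dict:
    """Recovery of a planted 50-gene set shifted by 1.5 SD, 20 vs 20.

    Reports the fraction of seeds where the planted set reaches
    q <= 0.05 with the correct direction, and the largest per-set
    false-recovery frequency among non-planted sets.
    """
    rng = np.random.default_rng(seed)
    recovered = 0
    false_counts: dict[str, int] = {}
    for _ in range(n_seeds):
        cfg = simulate.SimulationConfig(
            seed=int(rng.integers(2**31 - 1)), planted={"SET0001": (1.5, "up")}
        )
        m, ann, coll, _ = simulate.generate_expression(cfg)
        prof = faime_profile(m, coll)
        res = ztest_mechanisms(prof, ann, "tumor")
        res["q"] = adjust_by(res["p"])
        sig = build_signature(res)
        if "SET0001" in sig.mechanisms and sig.directions["SET0001"] == "up":
            recovered += 1
        for mech in sig.mechanisms - {"SET0001"}:
            false_counts[mech] = false_counts.get(mech, 0) + 1
    max_false = max(false_counts.values()) / n_seeds if false_counts else 0.0
    return {
        "recovery_rate": recovered / n_seeds,
        "max_false_recovery_rate": max_false,
        "n": n_seeds,
    }


def by_adjustment_benchmark(seed: int, n_random: int = 200) -> dict:
    """BY correctness: hand-computed example plus BH domination."""
    hand_err = float(np.abs(adjust_by([0.01, 0.02, 0.03]) - 0.055).max())
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_random):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 100)))
        q_by, q_bh = adjust_by(p), adjust_bh(p)
        if np.any(q_by < q_bh - 1e-12) or np.any(q_by < p - 1e-12):
            violations += 1
    return {"hand_example_max_error": hand_err, "domination_violations": violations,
            "n": n_random}


# ----------------------------------------------------------------- evaluation


def _signature_from_pipeline(prof, ann, fdr=0.05):
    res = ztest_mechanisms(prof, ann, "tumor")
    res["q"] = adjust_by(res["p"])
    return build_signature(res, fdr=fdr)


def clustering_benchmark(seed: int, n_seeds: int = 20, delta: float = 3.0) -> dict:
    """Diagnostic clustering at a strong planted effect.

    Plants one up- and one down-shifted 50-gene set at ``delta`` SD,
    derives the significant-mechanism signature, clusters the signature
    profile with all five algorithms and reports the minimum F-accuracy
    over algorithms and seeds.
    """
    rng = np.random.default_rng(seed)
    min_fa = 1.0
    for _ in range(n_seeds):
        cfg = simulate.SimulationConfig(
            seed=int(rng.integers(2**31 - 1)),
            planted={"SET0001": (delta, "up"), "SET0002": (delta, "down")},
        )
        m, ann, coll, _ = simulate.generate_expression(cfg)
        prof = faime_profile(m, coll)
        sig = _signature_from_pipeline(prof, ann)
        sub = prof.subset(sorted(sig.mechanisms))
        truth = ann.groups()
        for algo in CLUSTER_ALGORITHMS:
            fa = cluster_samples(
                sub, truth, algo, positive_class="tumor", seed=0
            ).f_accuracy
            min_fa = min(min_fa, float(fa))
    return {"min_f_accuracy": min_fa, "n": n_seeds}


def feature_permutation_benchmark(seed: int, n_resample: int = 999) -> dict:
    """Empirical-p floor for a reproducible modest-effect signature.

    Emulates the regime where the signature is a small fraction of a
    large mechanism universe: ten planted sets at 0.6 gene-noise SD
    (five up, five down) among 2000 mechanisms over 4000 genes.  The
    signature clusters samples far better than any same-sized random
    mechanism subset — a random draw carries at most a signal set or
    two diluted among null ones — so the feature-permutation p sits at
    its floor 1/(n+1).
    """
    planted = {
        f"SET{i + 1:04d}": (0.6, "up" if i % 2 == 0 else "down") for i in range(10)
    }
    cfg = simulate.SimulationConfig(
        seed=seed, n_genes=4000, n_sets=2000, planted=planted
    )
    m, ann, coll, _ = simulate.generate_expression(cfg)
    prof = faime_profile(m, coll)
    sig = _signature_from_pipeline(prof, ann)
    truth = ann.groups()
    sub = prof.subset(sorted(sig.mechanisms))

    def metric(p):
        return cluster_samples(
            p, truth, "ward-euclidean", positive_class="tumor"
        ).f_accuracy

    observed = metric(sub)
    p_emp = feature_permutation_p(
        observed, prof, len(sig), metric, n_resample=n_resample, seed=seed + 1
    )
    return {
        "p_empirical": float(p_emp),
        "floor": 1 / (n_resample + 1),
        "observed_f_accuracy": float(observed),
        "signature_size": len(sig),
        "n": n_resample,
    }


def permutation_exactness_benchmark(seed: int, n_mechanisms: int = 10) -> dict:
    """Exhaustive 3-vs-3 permutation p versus independent enumeration."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(0, 1, (n_mechanisms, 6))
    prof = MechanismProfile(
        pd.DataFrame(
            scores,
            index=[f"M{i}" for i in range(n_mechanisms)],
            columns=[f"s{j}" for j in range(6)],
        )
    )
    ann = SampleAnnotation(
        pd.DataFrame(
            {"sample_id": [f"s{j}" for j in range(6)],
             "group": ["a"] * 3 + ["b"] * 3}
        )
    )
    got = permutation_null(prof, ann, exhaustive=True, group_of_interest="a")

    # independent enumeration over all C(6,3) = 20 label splits
    expected = []
    for row in scores:
        stats = []
        for idx in combinations(range(6), 3):
            g1 = row[list(idx)]
            g2 = row[[j for j in range(6) if j not in idx]]
            se = math.sqrt(np.var(g1, ddof=1) / 3 + np.var(g2, ddof=1) / 3)
            stats.append(abs((g1.mean() - g2.mean()) / se))
        obs = stats[0]  # split (0,1,2) is the observed labelling
        expected.append(sum(s >= obs - 1e-12 for s in stats) / 20)
    return {
        "max_abs_error": float(np.abs(got.to_numpy() - np.asarray(expected)).max()),
        "n": n_mechanisms,
    }


# -------------------------------------------------------------------- survival


def survival_benchmark(seed: int, n_seeds: int = 20, n_patients: int = 200) -> dict:
    """End-to-end prognostic recovery with a planted hazard.

    Each seed simulates two tumor cohorts (hazard coefficient 1.0 on
    the planted mechanism's latent score, 30% censoring) and checks:
    (a) the per-cohort Cox sign of the planted mechanism, (b) whether
    the planted mechanism ranks first by the signed Stouffer meta-p
    across both cohorts, and (c) whether the k = 2 medoid partition on
    the planted-mechanism profile separates survival (log-rank
    p < 0.05, first cohort).
    """
    rng = np.random.default_rng(seed)
    sign_ok = 0
    rank_first = 0
    logrank_sig = 0
    for _ in range(n_seeds):
        per_cohort = []
        signs = []
        first = None
        for c in range(2):
            cfg = simulate.SimulationConfig(
                seed=int(rng.integers(2**31 - 1)),
                n_tumor=n_patients,
                n_control=2,
                n_sets=50,
                hazard_coef=1.0,
                censoring_fraction=0.3,
            )
            m, ann, coll, truth = simulate.generate_expression(cfg)
            surv = simulate.generate_survival(truth, cfg)
            prof = faime_profile(m, coll)
            patient = prepare_patient_profiles(prof, ann)
            cox = cox_per_mechanism(patient, surv)
            per_cohort.append(cox)
            signs.append(float(cox.loc["SET0001", "direction"]))
            if c == 0:
                first = (patient, surv)
        if all(s > 0 for s in signs):
            sign_ok += 1
        meta = meta_analyze(per_cohort)
        if meta.index[0] == "SET0001":
            rank_first += 1
        patient, surv = first
        groups = clara_partition(patient.subset(["SET0001"]), k=2, seed=0)
        tab = surv.table.copy()
        tab["group"] = tab["patient_id"].map(groups)
        if km_logrank(SurvivalTable(tab))["p"] < 0.05:
            logrank_sig += 1
    return {
        "cox_sign_rate": sign_ok / n_seeds,
        "stouffer_rank_first_rate": rank_first / n_seeds,
        "logrank_significant_rate": logrank_sig / n_seeds,
        "n": n_seeds,
    }


def stouffer_benchmark() -> dict:
    """Normal-quantile arithmetic of the signed Stouffer combination."""
    from .survival import p_to_z, stouffer_meta

    z = p_to_z(0.05, +1, one_sided=True)
    z_meta, _ = stouffer_meta([z, z])
    z_cancel, _ = stouffer_meta([z, -z])
    return {
        "z_single": float(z),
        "z_meta_same_direction": float(z_meta),
        "one_sided_p": float(norm.sf(z_meta)),
        "z_meta_opposite": float(z_cancel),
    }


def logrank_oracle_benchmark() -> dict:
    """Toy two-group table versus a hand-computed log-rank statistic."""
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    groups = ["a", "b", "a", "b", "a", "b"]
    table = SurvivalTable(
        pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(6)],
                "time": times,
                "event": [1] * 6,
                "group": groups,
            }
        )
    )
    got = km_logrank(table)["statistic"]

    # hand computation: one event per risk set, no censoring
    o_minus_e, var = 0.0, 0.0
    at_risk = list(zip(times, groups))
    for t, g in sorted(at_risk):
        n = len(at_risk)
        n_a = sum(1 for _, gg in at_risk if gg == "a")
        e_a = n_a / n
        o_minus_e += (1.0 if g == "a" else 0.0) - e_a
        if n > 1:
            var += e_a * (1 - e_a)
        at_risk = [(tt, gg) for tt, gg in at_risk if tt > t]
    expected = o_minus_e**2 / var
    return {"statistic": float(got), "expected": float(expected),
            "abs_error": abs(float(got) - expected)}


def pc1_concordance_benchmark(seed: int, n_seeds: int = 20) -> dict:
    """|Spearman rho| between a planted mechanism's score and PC1 of its genes."""
    rng = np.random.default_rng(seed)
    rhos = []
    for _ in range(n_seeds):
        cfg = simulate.SimulationConfig(
            seed=int(rng.integers(2**31 - 1)),
            n_sets=50,
            planted={"SET0001": (2.0, "up")},
        )
        m, ann, coll, _ = simulate.generate_expression(cfg)
        prof = faime_profile(m, coll)
        tumors = [
            s for s, g in ann.groups().items() if g == "tumor"
        ]
        sub = ExpressionMatrix(m.values[tumors])
        out = pca_pc1_check(
            sub, coll["SET0001"].members, prof.scores.loc["SET0001", tumors]
        )
        rhos.append(abs(out["spearman_rho"]))
    return {"min_abs_spearman_rho": float(min(rhos)),
            "mean_abs_spearman_rho": float(np.mean(rhos)), "n": n_seeds}
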