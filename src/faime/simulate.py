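"""Synthetic expression cohorts with known ground truth.

Emulates the study design the downstream modules expect: a log2
expression matrix over tumor and control samples (optionally paired),
a gene-set collection in which chosen sets are planted with an up- or
down-shift of their member genes in tumors, and right-censored survival
outcomes whose log-hazard is proportional to a planted mechanism's
latent score.  Gene values are Gaussian on the log2 scale (mechanism
scores of real arrays are themselves near-normal); a heavy-tailed
Student-t option is available for robustness checks.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, SampleAnnotation
from .survival import SurvivalTable

__all__ = ["SimulationConfig", "GroundTruth", "generate_expression", "generate_survival"]


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults describe a mid-sized two-group microarray comparison:
    1000 genes, 200 mechanisms of 10-50 genes, 20 tumors vs 20 controls.
    Between-gene baseline spread (SD 2 log2 units) dominates
    between-sample noise (SD 0.4), as in real log2 intensity data, so
    samples of one phenotype share a coherent expression profile.  One
    planted 50-gene set is shifted by ``delta`` gene-noise SD units in
    tumors, with a per-patient activity effect shared across the set's
    genes.  Survival: exponential event times (months) with log-hazard
    = ``hazard_coef`` x standardized latent mechanism score and 30%
    censoring.
    """

    n_genes: int = 1000
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 50)
    n_tumor: int = 20
    n_control: int = 20
    paired: bool = False
    planted: dict[str, tuple[float, str]] = field(
        default_factory=lambda: {"SET0001": (1.5, "up")}
    )  # set id -> (shift in noise-SD units, "up"|"down")
    planted_size: int = 50
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.4
    patient_effect_sd: float = 0.5
    planted_activity_sd: float = 0.5  # per-patient spread of planted-set activity
    heavy_tails: bool = False  # Student-t with 5 df instead of Gaussian noise
    baseline_hazard: float = 1 / 30.0  # events per month
    hazard_coef: float = 1.0
    censoring_fraction: float = 0.3
    seed: int = 0
    collection_seed: int | None = None  # share one gene-set collection across cohorts

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring fraction must be in [0, 1)")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("invalid set-size range")
        if self.planted_size > self.n_genes:
            raise ValueError("planted set larger than the gene universe")
        for sid, (delta, direction) in self.planted.items():
            if not np.isfinite(delta):
                raise ValueError(f"planted shift for {sid} must be finite")
            if direction not in ("up", "down"):
                raise ValueError(f"direction for {sid} must be 'up' or 'down'")


@dataclass
class GroundTruth:
    """What was planted: set directions, per-patient latent scores,
    and the true hazard coefficient."""

    planted: dict[str, str]  # set id -> direction
    latent_scores: pd.Series  # per tumor patient, standardized
    hazard_coef: float


def _noise(rng: np.random.Generator, shape, sd: float, heavy: bool) -> np.ndarray:
    if heavy:
        df = 5
        return rng.standard_t(df, size=shape) * sd / np.sqrt(df / (df - 2))
    return rng.normal(0.0, sd, size=shape)


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, GeneSetCollection, GroundTruth]:
    """Simulate a log2 expression matrix with planted deregulated sets.

    Gene g's baseline is drawn once from N(baseline_mean, baseline_sd)
    and shared by all samples; per-sample noise has SD ``noise_sd``.
    Members of a planted set are shifted by ``+/- delta * noise_sd`` in
    tumor samples.  In paired mode each synthetic patient contributes
    one control and one tumor sample sharing a patient random effect.
    The per-patient latent score is the patient's average planted-gene
    deviation, standardized across tumor patients.
    """
    rng = np.random.default_rng(config.seed)
    rng_coll = (
        rng
        if config.collection_seed is None
        else np.random.default_rng(config.collection_seed)
    )
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    # gene-set collection; the planted sets take the first slots
    sets: list[GeneSet] = []
    planted_dirs: dict[str, str] = {}
    lo, hi = config.set_size_range
    for i in range(config.n_sets):
        sid = f"SET{i + 1:04d}"
        if sid in config.planted:
            size = config.planted_size
        else:
            size = int(rng_coll.integers(lo, hi + 1))
        members = rng_coll.choice(genes, size=size, replace=False)
        sets.append(GeneSet(sid, f"synthetic set {i + 1}", "custom", frozenset(members)))
    collection = GeneSetCollection(sets)
    for sid in config.planted:
        if sid not in collection:
            raise ValueError(f"planted id {sid!r} not among generated sets")
        planted_dirs[sid] = config.planted[sid][1]

    n_t, n_c = config.n_tumor, config.n_control
    if config.paired and n_t != n_c:
        raise ValueError("paired design requires equal group sizes")
    tumor_ids = [f"T{j:03d}" for j in range(n_t)]
    control_ids = [f"C{j:03d}" for j in range(n_c)]
    samples = control_ids + tumor_ids

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    x = baseline[:, None] + _noise(
        rng, (config.n_genes, n_c + n_t), config.noise_sd, config.heavy_tails
    )
    if config.paired:
        eff = rng.normal(0.0, config.patient_effect_sd, size=(config.n_genes, n_t))
        x[:, :n_c] += eff
        x[:, n_c:] += eff

    # planted shift: direction * delta plus a per-patient activity effect
    # shared by all of a set's genes (tumors vary in mechanism activity)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for sid, (delta, direction) in config.planted.items():
        sgn = 1.0 if direction == "up" else -1.0
        activity = sgn * delta + rng.normal(0.0, config.planted_activity_sd, size=n_t)
        idx = [gene_pos[g] for g in collection[sid].members]
        x[np.ix_(idx, range(n_c, n_c + n_t))] += activity[None, :] * config.noise_sd

    matrix = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))

    rows = []
    for j, sid in enumerate(control_ids):
        rows.append((sid, "control", f"P{j:03d}" if config.paired else np.nan, np.nan))
    for j, sid in enumerate(tumor_ids):
        pid = f"P{j:03d}"
        rows.append((sid, "tumor", pid if config.paired else np.nan, pid))
    annotation = SampleAnnotation(
        pd.DataFrame(rows, columns=["sample_id", "group", "pair_id", "patient_id"])
    )

    # latent score: mean deviation from baseline over planted genes, per tumor
    planted_genes = sorted(
        {g for sid in config.planted for g in collection[sid].members}
    )
    if planted_genes:
        idx = [gene_pos[g] for g in planted_genes]
        dev = (x[np.ix_(idx, range(n_c, n_c + n_t))] - baseline[idx, None]).mean(axis=0)
        sd = dev.std(ddof=0)
        latent = (dev - dev.mean()) / sd if sd > 0 else dev * 0.0
    else:
        latent = np.zeros(n_t)
    pids = [annotation.table.set_index("sample_id").loc[s, "patient_id"] for s in tumor_ids]
    truth = GroundTruth(
        planted=planted_dirs,
        latent_scores=pd.Series(latent, index=pids, name="latent"),
        hazard_coef=config.hazard_coef,
    )
    return matrix, annotation, collection, truth


def _calibrate_censor_rate(event_times: np.ndarray, target: float) -> float:
    """Rate of an exponential censoring time giving the target fraction.

    Solves E[P(C < T)] = target over the sampled event times by
    bisection; P(C < t) = 1 - exp(-rate * t) for exponential C.
    """
    if target <= 0:
        return 0.0

    def frac(rate: float) -> float:
        return float(np.mean(1 - np.exp(-rate * event_times)))

    lo_r, hi_r = 1e-9, 1e-9
    while frac(hi_r) < target:
        hi_r *= 2
        if hi_r > 1e9:
            break
    for _ in range(200):
        mid = (lo_r + hi_r) / 2
        if frac(mid) < target:
            lo_r = mid
        else:
            hi_r = mid
    return (lo_r + hi_r) / 2


def generate_survival(truth: GroundTruth, config: SimulationConfig) -> SurvivalTable:
    """Exponential event times with log-hazard proportional to the latent score.

    Event time T_i ~ Exp(rate = baseline_hazard * exp(coef * score_i));
    independent exponential censoring calibrated so the expected
    censored fraction matches ``censoring_fraction``.  Times in months.
    """
    scores = truth.latent_scores
    if scores.empty:
        raise ValueError("ground truth carries no latent scores")
    rng = np.random.default_rng(config.seed + 1)
    rate = config.baseline_hazard * np.exp(config.hazard_coef * scores.to_numpy(float))
    if not np.all(np.isfinite(rate)) or np.any(rate <= 0):
        raise ValueError("degenerate hazard rates; check baseline_hazard and coefficient")
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_fraction > 0:
        c_rate = _calibrate_censor_rate(t_event, config.censoring_fraction)
        t_cens = rng.exponential(1.0 / c_rate, size=len(t_event))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    return SurvivalTable(
        pd.DataFrame({"patient_id": scores.index, "time": time, "event": event})
    )
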