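# Methods

## Scoring model

A sample's expression vector over the measured gene universe *G* is
reduced to ranks (1 = highest).  The weight of rank *r* is
`w(r) = exp(-decay * r / |G|)`; `decay` (default 1, dimensionless)
sets how many e-folds the weight falls across the ranked list.  The
weight function is a single module-level function
(`faime.core.rank_weight`), deliberately the only place the weighting
scheme lives, so an alternative exponential form can be substituted
without touching anything else.

The weighted expression of a gene is `w * x` (its log2 value times its
rank weight).  A documented alternative (`weight_only=True`) scores
with the weights alone, making the score a pure rank statistic; the
product form is the default because the normalized centroid is defined
over *weighted expression*, not weights.  The normalized centroid of a
subset is the arithmetic mean of its members' weighted expression, and
a gene set's score is NC(set) − NC(complement), both restricted to the
measured universe.  Two exact identities follow and are enforced by
tests: conservation, |S|·NC(S) + |G∖S|·NC(G∖S) = Σ w·x, and rank
invariance, any strictly increasing transform of a sample's expression
leaves ranks and weights bit-identical.

Ties in expression receive consecutive ranks in gene-id order by
default (deterministic, reproducible across runs); mid-rank averaging
is available (`tie_method="average"`).  Missing values: a gene missing
in a sample is dropped from that sample's universe, so |G| and the
weights are per-sample; a profile is computed for every sample
independently, which is the method's defining property (removing any
other sample leaves a sample's scores bit-identical — tested).

## Pre-scoring filters

Probe-level matrices are collapsed to genes by keeping, per gene, the
probe with the largest IQR across samples (linear-interpolation
quantiles; ties broken by smallest probe id), then dropping genes
whose winning probe has negative mean log2 expression over **all**
samples (the within-group alternative was considered and rejected:
the filter describes array-wide detectability, not phenotype).  Rows
with more than 50% missing values are dropped with a warning.  Gene
sets are intersected with the measured universe and kept only with at
least `min_genes = 4` measurable members (strictly more than 3);
downstream scoring uses the intersected membership.

## Deregulation calling

Per mechanism, scores are compared between two phenotype groups with a
Z-test — unpaired `(m1-m2)/sqrt(s1²/n1 + s2²/n2)` or paired
`mean(d)/(sd(d)/sqrt(n))` — using sample standard deviations; a
t-variant is deliberately not silently substituted.  The empirical p
re-permutes the phenotype labels (independent within-pair sign flips
when paired) and recomputes *all* mechanism statistics jointly per
permutation, preserving the between-mechanism correlation inherited
from shared genes; `(1 + b)/(n_perm + 1)` avoids zero p-values.  For
designs small enough to enumerate, `exhaustive=True` replaces sampling
with the complete set of label splits and the exact tie-inclusive
fraction.  A pooled-null variant (one shared null across mechanisms)
is available behind a flag; per-mechanism is the default.

Multiple testing uses Benjamini–Yekutieli (statsmodels), valid under
arbitrary dependence — the mechanism scores of overlapping sets are
strongly dependent.  The signature at FDR 5% is called on the
BY-adjusted **analytic** p, with the permutation p reported alongside:
an n-permutation empirical p is floor-limited at 1/(n+1), which after
BY inflation can never reach 0.05 at realistic mechanism counts, so
adjusting it would make the procedure vacuous.  GO-graph redundancy is
pruned by partitioning significant terms into connected components of
the ontology graph's undirected skeleton restricted to significant
nodes and keeping each component's smallest-q term (ties by id).

Cross-dataset overlap is |∩|/|∪| over k signatures, with an empirical
p from resampling same-sized term sets from each dataset's tested
universe without replacement.  Precision–recall curves are computed at
every prefix of a ranked term list against a proxy gold standard.

## Diagnostic evaluation

Five unsupervised algorithms partition samples from the signature
profile: Ward and average linkage on euclidean distances, centroid
linkage on correlation distances (1 − Pearson) with and without
per-sample standardization, and k-medoids (k = 2).  The "first two-way
partition" of a hierarchical tree is the cut at two clusters.  Note
that centroid linkage is formally defined for euclidean geometry;
applying it to a correlation-distance matrix mirrors a widely used
microarray-software option and is retained for comparability.
Clusters are mapped to class labels by within-cluster majority (an
accuracy-maximising bijection resolves the degenerate two-cluster
tie), and quality is summarised as the F-accuracy: the harmonic mean
of precision and recall for the positive class, with plain accuracy
available behind a flag.

The cross-validated AUC uses a fixed nearest-centroid scorer
(out-of-fold score = distance to negative centroid − distance to
positive centroid) inside 100 runs of stratified 5-fold CV.  The
scorer is parameter-free by design: the repeated CV then measures the
separability of the profile subset rather than classifier tuning.
Feature-permutation significance redraws `n` random mechanism subsets
of the signature's size from the full profile and reports
`(1 + #{metric ≥ observed})/(n + 1)`.

k-medoids is hand-implemented (no installed package provides it): the
exact PAM objective is solved by enumeration whenever C(n, k) ≤ 3·10⁵,
otherwise by greedy BUILD plus full SWAP descent.  Patient
partitioning ("CLARA") uses the same solver — CLARA's subsampling is
an approximation needed only at scales far beyond the cohort sizes
this package targets.

## Survival analysis

Duplicate samples of a patient are averaged mechanism-wise before any
survival computation (one independent measure per patient).  Patients
are partitioned by k-medoids on their signature profiles (k = 2 or 3)
and compared with Kaplan–Meier curves and the log-rank test
(lifelines).  Per-mechanism prognosis is a univariate Cox
proportional-hazards fit (Efron ties) of time-to-event on the
mechanism score, restricted to mechanisms with ≥ 4 measurable member
genes; non-converging fits are flagged, never dropped silently.
Cohorts are combined by signed Stouffer Z — the sign convention is
positive = higher score, higher hazard, applied per cohort before
summation — with a two-sided joint p (the direction is reported
separately) and Bonferroni adjustment over the mechanisms measurable
in every cohort.  The PC1 cross-check computes the first principal
component of a set's member-gene expression across patients
(sign-oriented to correlate non-negatively with the set's mean
expression), its Spearman correlation with the mechanism scores, and
a Cox fit on PC1.

## Synthetic cohorts

`faime.simulate` emulates a two-group log2 microarray study: per-gene
baselines N(7, 2) shared by all samples, between-sample gene noise
N(0, 0.4), optional Student-t(5) noise for robustness checks, and an
optional shared patient effect for paired designs.  The baseline
spread deliberately dominates the noise, as in real log2 intensity
data; this is what gives samples of one phenotype a coherent profile
shape, without which correlation-distance clustering has nothing to
work with.  Planted sets shift their members in tumors by
`delta` gene-noise SD units (so `delta` is a detectability unit
independent of the baseline scale) plus a per-patient activity effect
(SD 0.5 noise units, shared across the set's genes) — tumors vary in
how strongly a mechanism is activated, which is what makes
per-patient survival modelling meaningful.  The latent score of a
tumor patient is the standardized mean deviation of the planted genes
from baseline.  Event times are exponential with rate
`baseline_hazard * exp(coef * latent)`; censoring times are
exponential with their rate calibrated by bisection so the expected
censored fraction matches the request.  Everything is deterministic
given the seed; a `collection_seed` lets several cohorts share one
gene-set collection for cross-dataset protocols.

What the generator does **not** emulate: probe saturation, batch and
spatial artifacts, correlated gene-gene co-expression modules beyond
the planted activity factor, and non-exponential hazards.  Passing
tests therefore demonstrate correctness of the algorithms under a
clean generative model, not performance on any real cohort.

## Validation suite and problem sizes

`faime.validation` fixes one study condition per property:
scoring-oracle agreement on 200 random instances (|G| ≤ 12, ≤ 4 sets)
against an independent plain-loop reference; null false-positive
control over 200 datasets (20 vs 20, 200 mechanisms) with a KS
uniformity check of the permutation p; planted-set recovery over 100
seeds (50-gene set, delta = 1.5, 20 vs 20); clustering robustness over
20 seeds at delta = 3; the feature-permutation floor in a
small-signature regime (10 sets at delta = 0.6 among 2000 mechanisms
over 4000 genes — a strong-effect regime cannot show the floor, since
any random draw containing a planted set clusters perfectly); survival
recovery over 20 seeds (two cohorts of 200 patients, hazard
coefficient 1.0, 30% censoring); and PC1 concordance over 20 seeds.
These sizes keep the whole suite within a few minutes on one CPU while
leaving the pass/fail margins wide.

## Known limitations

Signed/bidirectional set variants (up- and down-sub-scores within one
set) are out of scope; the score assumes sets deregulated
predominantly in one direction.  The Z-test relies on approximate
normality of scores across samples — reasonable for sets of ≥ 4 genes
by central-limit behaviour, checked empirically on the synthetic
model only.  The CV classifier inside the AUC is a fixed
nearest-centroid rule by choice; absolute AUCs are not comparable to
tuned classifiers.  `delta` is expressed in gene-noise SD units, so
comparisons across noise models require care.
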