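# Methods

## The synthetic study generator

The generator (`fibromark.synthgen`) emulates a two-arm dietary NASH study:
a control and a diseased diet group of `animals_per_group` (default 8)
animals each, profiled at several weeks (default 4/8/12). Liver RNA covers
all weeks; liver and plasma proteomics cover the final week only, split
over `batches` (default 2) runs balanced across arms — mirroring a design
in which proteomics is acquired once, at the terminal time point, in
multiplexed batches.

**Latent severity and fibrosis.** Each animal carries a latent disease
severity: ~0 for controls, ramping linearly to 1 with week for the diseased
arm, plus Gaussian noise (`severity_noise_sd`, default 0.1). The histology
fibrosis score is an affine map of severity plus noise
(`fibrosis_noise_sd`, default 0.5), rounded and clipped to an ordinal 0–4
scale. Common staging systems use 0–4; the scale is configurable
(`fibrosis_max`) because published studies differ.

**Feature classes.** Genes partition into `null`, `liver_de_only`
(default 35%), `secreted_biomarker` (1%), and `antiregulated` (1.5%); the
non-null fractions approximate the heavy regulation seen in severe dietary
models (most detected liver proteins regulated; anti-regulated
transcript–protein pairs are a ~1–2% minority). Non-null genes get an RNA
effect `beta` (log2 per unit severity) with magnitude uniform in
[0.5, 1.5] × `effect_size_log2` (default 2.0, matching liver fold changes
spanning ±5 log2) and random sign; planted biomarkers are always
up-regulated so their fibrosis correlation is positive.

**RNA counts.** Negative-binomial via a gamma–Poisson mixture: log2 mean =
per-gene baseline (Normal(6, 1.5²)) + `beta`·severity; dispersion 0.1.
Counts-vs-intensity asymmetry between RNA-Seq and proteomics is preserved
on purpose: the RNA chain is CPM-normalized and the protein chain
intensity-normalized, as with real data.

**Protein coupling.** The liver protein effect is
`c·beta + sqrt(1−c²)·eps` with coupling `c = rna_protein_coupling`
(default 0.75, the magnitude of published transcript–protein fold-change
correlations in this setting). `eps` is confined to non-null genes (nulls
stay null everywhere), residualized against `beta` and rescaled so the
realized sample correlation between the RNA and protein effect vectors over
all features equals `c` exactly — the parameter is a correlation target,
not merely an expectation. Anti-regulated genes flip the protein effect's
sign. Plasma intensities couple to the liver protein effect only for
planted secreted biomarkers, attenuated by `plasma_attenuation`
(default 0.7); all other plasma proteins are decoupled (null).

**Missingness and batches.** Protein matrices receive left-censored
missingness: entries go missing with logistic probability decreasing in
log2 intensity (`censoring_steepness` 1.5), with the logistic midpoint
solved by bisection so the overall missing fraction matches `missing_rate`
(default 2%, near the 0.5–1.5% seen in deep TMT data). Per-feature,
per-batch Gaussian offsets (SD 0.3 log2) model run effects.

**Prior evidence.** Per gene: a disease-association score in [0, 1]
(Beta(1.2, 6) background), long-tailed publication counts
(negative-binomial), a positive expected count (log-normal), and two binary
flags. A configurable fraction (default 0.8) of true planted biomarkers
receives elevated evidence; with the fraction at 0 the table is fully
decoupled from the data, which is what lets prior-knowledge-only and
data-driven rankings disagree.

**What the generator does not emulate.** No peptide/spectrum level, no
isotope impurity or ratio compression, no library-size or GC biases in
RNA-Seq, no correlated gene modules (features are independent given the
severity axis), and no inter-animal covariance beyond the single latent
severity. Passing recovery tests therefore demonstrates that the pipeline's
logic recovers planted structure under realistic noise, censoring and batch
effects — not that it is robust to every artefact of real instruments.

## Preprocessing

* **Presence filter:** keep features with ≥ `min_present` (default 6)
  observed values in at least one group of (default) 8 replicates.
* **Normalization:** divide each column by its total (equal loading),
  rescale so every column's observed mean equals `target_mean` (100) — the
  channel-average convention of multiplexed proteomics.
* **Imputation:** missing log2 entries in column *j* are drawn from
  Normal(mean_j − downshift·sd_j, (width·sd_j)²) with downshift 2.5 and
  width 0.2 — "downshift" and "width" read as multiples of the per-column
  observed SD in log2 space, the convention the stated magnitudes imply.
  The model is missing-not-at-random: censored values live in the low tail.
* **Batch centering:** each feature is mean-centered within each run. The
  text this mirrors says only that "each run was mean centered";
  per-feature-within-batch centering is the interpretation that actually
  removes the additive run offsets the generator plants, so it is the
  default and the documented reading.
* **RNA:** CPM with column sums of exactly 10⁶; a gene is "expressed" if
  CPM ≥ 1 in strictly more than half the samples of at least one group
  ("majority" read strictly; a 4-of-8 gene is not expressed).

A note on total-intensity normalization: with heavy asymmetric regulation,
dividing by column totals shifts all features of a sample by a common
factor (a compositional effect), so some truly-null features acquire small
apparent fold changes. This mirrors real TMT data processed the same way;
it adds a shared additive constant in log2 space and therefore does not
bias correlation-based quantities (coupling recovery, fibrosis r²), but it
does inflate regulated-feature counts, as it would in a real study.

## Differential statistics

Pooled-variance Student t (two-sided) per feature on log2 data — pooled
rather than Welch to match the named test; Welch is available via a flag.
BH step-up adjustment. The permutation FDR is SAM-style with s0 = 0:

    q_i = E_perm[#{null |t| ≥ |t_i|}] / #{observed |t| ≥ |t_i|}

monotonized step-up style (each feature takes the minimum raw q among
features with smaller-or-equal |t|) and capped at 1. Sampled permutations
are balanced — each permuted group draws proportionally from both original
groups — so genuine group effects cancel in the null statistics; when
`n_perm` reaches the number of distinct label arrangements, all
arrangements are enumerated and the result is seed-independent. Features
with zero pooled variance get NaN p (with a warning) and q = 1.

Regulation calls use padj < 0.01 and |log2FC| ≥ 1 (boundary inclusive on
the fold change). Time-profile clustering z-scores each feature's log-ratio
time course and applies average-linkage agglomerative clustering on
Euclidean distances; constant profiles are excluded and reported.
Overrepresentation is a one-sided hypergeometric upper tail against the
expressed-gene background with BH across terms.

## Fibrosis correlation and concordance

Per-feature Pearson correlation (the fibrosis score treated as numeric;
Spearman available) with pairwise-complete handling of missing proteomics
values — no imputation enters the correlation subscore. Constant inputs
give r = NaN with r² reported 0 and a flag. Concordance classes between two
contrasts: co-regulated (both significant, same sign), anti-regulated
(both significant, opposite signs), single, none.

## Ranking

Subscore commensurability is the one genuinely open design point: the
method sums subscores of mixed scales (unbounded dge scores, r² in [0, 1],
binary flags). Decision: the three dge subscores and the two literature
inputs are rank-normalized to [0, 1] over the candidate cohort
((rank − 1)/(n − 1), average ranks for ties, 0.5 for a single candidate);
r², the association score and the flags enter raw; each dimension score is
the **mean** of its subscores so all four dimensions live in [0, 1] and the
weight settings are comparable. A raw-sum mode (`aggregation="sum"`)
reproduces the literal sum-of-subscores reading; the two modes give the
same ranking under unit-vector weights but can differ under mixed weights,
and neither claims numeric identity with any published score values.
The candidate filter (human ortholog + detected in both protein matrices)
is applied before any rank normalization, so normalization cohorts equal
the candidate set. Missing prior evidence is zero evidence, never
missing-at-random. Final ranks are 1-based, descending by total score, ties
broken lexicographically by candidate id.

## Marker validation

PCA is exact SVD on the imputed (fully observed) log2 matrix with features
mean-centered — a deliberate substitution for probabilistic PCA: the
pipeline already defines imputation, and exact SVD is deterministic and
testable. Component signs follow the largest-|loading|-positive convention
so scores are reproducible. Marker validation regresses each of the first
three liver PCs on a marker's per-sample plasma intensity; r² equals the
squared Pearson correlation (simple-regression identity, asserted in
tests). Tissue enrichment divides a gene's per-tissue median expression by
the median of its per-tissue medians (a geometric-mean denominator is
available via `denominator="geomean"`; with multiplicative expression data
the two can disagree, so both readings are offered and the median version
is the default).

## Orchestration and reproducibility

`run_pipeline` derives per-stage seeds from one global seed by hashing the
stage name (seeds stay below 2³¹), records every stage's parameters and
outputs in a JSON manifest, writes all tables with fixed column order and
6-significant-digit formatting, and is byte-reproducible for a fixed
(config, seed). The manifest includes a recovery report (planted markers in
the default top-k) whenever the study comes from the generator.

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen so the whole suite completes
in minutes on one CPU: FDR calibration at 1000 features × 8 vs 8 × 1000
permutations × 20 study replicates; coupling recovery at 3000 genes;
ranking recovery at 2000 genes / 400 plasma proteins / 10 planted markers ×
20 replicates; PC-regression structure at 1000 genes × 20 replicates.

## Known limitations

* The permutation-FDR power check documents a sharp edge: at 8 vs 8 with a
  4-SD effect the per-feature detection probability at q < 0.01 is ~99.6%,
  so requiring *all* of 50 planted features simultaneously succeeds in only
  ~83–87% of replicates (0.996⁵⁰), not ≥95% — the minimum over many
  features is harsher than per-feature power. The corresponding acceptance
  test states the stricter bound and fails it honestly; typical recovery is
  48–50 of 50.
* Pearson on an ordinal 0–4 score is a linearity approximation; Spearman is
  offered but cumulative-link models are out of scope.
* The ranking treats subscores as exchangeable within a dimension; no
  learned weighting is attempted.
* No cross-species translation is modelled: orthology is an input table.
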