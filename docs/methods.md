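# Methods

This note documents the models implemented in `vulnscan`, the conventions
chosen where several readings were possible, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter.

## Study design assumed

A cohort of several mutant genotypes and one wild-type control, each profiled
by scRNA-seq in one or more experimental runs. Cells carry cluster labels
(cell types) produced upstream; clustering, batch correction, doublet removal
and ambient-RNA cleanup are out of scope here and the labels are taken as
given. The control genotype is named `"control"` throughout and every
contrast is mutant-vs-control within one cluster.

## QC and normalization (`preprocess`)

Cells are filtered on detected genes, total counts, and mitochondrial
percentage. Two presets are shipped: a whole-cell preset
(200–7000 genes, 500–30000 counts, mito < 15%) and a single-nucleus preset
(500–7000 genes, 1000–30000 counts, mito < 5%; nuclei carry few
mitochondrial transcripts, so a stricter bound is informative). Conventions
chosen where the bounds were ambiguous: gene/count bounds inclusive,
mitochondrial bound strict ("below"), and mito% computed on raw counts
before any filtering. Filtering is idempotent and reports the first failing
rule per removed cell.

Normalization follows the standard scale-and-regress chain: per-cell scaling
to 10⁴ total counts, log1p, per-gene OLS residuals against total counts and
mito% (the nuisance covariates), z-scoring, and clipping at +10. Residuals
are exactly orthogonal to the covariates before clipping; genes with
numerically zero residual spread are set to zero rather than z-scored, which
would only amplify floating-point noise.

## Differential expression (`detest`)

**Rank-sum route.** Two-sided Wilcoxon rank-sum per gene on log-normalized
expression, vectorized across genes; exact p-values when both groups are
small and tie-free, the tie-corrected normal approximation otherwise. Genes
constant across both arms get p = 1 and lfc = 0 (no evidence either way).
`lfc = log2((mean_mut + ε)/(mean_ctl + ε))` with ε = 1e-9. Contrasts with
fewer than 3 cells in an arm are skipped with a warning. BH adjustment over
genes.

**Pseudobulk NB route.** Counts of all cells sharing a run are summed;
pseudobulks under 10 cells are dropped. Each gene is modeled as NB2 with a
log link, a genotype indicator and a log-library-size offset. The dispersion
is estimated per gene by profile maximum likelihood (golden-section search on
log α over [1e-8, 100]; the group-rate MLE inside the profile is a damped
Newton solve), with no shrinkage across genes. This is deliberately a plain,
self-contained NB GLM rather than a DESeq2 re-implementation: no dispersion
shrinkage, no Cook's filtering, no independent filtering. The Wald statistic
for the genotype coefficient is referred to a t distribution with
`n_pseudobulks − 2` degrees of freedom rather than a normal: with the
handful of pseudobulks a run-based design yields, the ML dispersion estimate
is biased low and a normal reference is anticonservative; the t reference
keeps the null rejection rate near nominal (checked by simulation in the test
suite: ~0.067 at nominal 0.05 with 4+4 pseudobulks). Zero-count arms are
floored at half a count per library so coefficients stay finite with
commensurately wide intervals.

**Signed significance.** `score = lfc × (−log₁₀ p)`, p floored at 1e-300.
The sign convention puts significant upregulated genes at large positive
scores. (A literal product of lfc and log p would invert the sign for
significant genes; the intent — concordant ranking of up- vs downregulated
genes — requires the −log₁₀ form.) Method concordance is the Spearman
correlation of the two routes' signed scores on their shared genes.

**Downsampling.** `downsample_cluster` draws a seeded uniform subset of n
cells per genotype arm within a cluster, for size-bias control experiments.
The DEG count (`count_deg`) uses adjusted p < 0.05 by default; the threshold
is a parameter since different designs justify different cutoffs.

## The vulnerability model (`vulnmodel`)

NB2 regression of the per-cluster DEG count on `log(min(x1, x2))` — the
smaller arm limits power, hence the min; natural log by convention. Fitting
is by full ML (statsmodels `NegativeBinomial`), jointly over intercept,
slope and dispersion. Per-cluster UMI depth is deliberately *not* a
covariate: it correlates with cell size and would absorb biological signal.
When all clusters share the same `min(x1, x2)` the slope is unidentifiable
and the intercept-only model is fit with `b1 = 0`. Residuals are reported
raw (`r = y − μ̂`; positive = more DEGs than the cluster's size predicts) and
as Pearson residuals `r/√(μ̂ + αμ̂²)`; ranking uses raw residuals by default,
Pearson behind a flag, because the raw difference is the quantity of
interest even though Pearson stabilizes variance.

Consensus across genotypes: within each genotype clusters are ranked by
residual descending (average ranks on ties); clusters missing from a
genotype get that genotype's worst rank; clusters are sorted by mean rank and
the top k form the "commonly affected" set. Mean rank was chosen as the
combination rule because it is symmetric in genotypes, insensitive to the
residuals' genotype-specific scales, and degenerates gracefully to a single
genotype's own ranking.

## Convergence (`convergence`)

Per genotype, genes are ranked by signed significance (rank 1 = most
upregulated, average ranks on ties) on the intersection of the genotypes'
gene universes — summed ranks are incomparable with missing entries, so the
intersection is the only safe universe. Ranks are summed and genes sorted
ascending; the first and last `ceil(f·n)` genes are the common up/down sets
(default f = 0.05; f > 0.5 would overlap and is rejected). Ties at tail
boundaries break lexicographically on gene id for determinism. Ranks are
computed over all genes rather than significant genes only, keeping ranks
dense and the tail sizes predictable.

## Cross-species operations (`xspecies`)

Orthologue maps carry integer confidence scores; pairs under the minimum
score (default 5) are ignored, and a gene with several admissible partners
maps to the best-scoring one (ties lexicographic). Overlap of a mapped gene
set with another species' DEG list is `k/n` with an upper-tail
hypergeometric p. The universe is an explicit, required argument — overlap
p-values are only meaningful relative to a stated universe (the genes
testable in both species is the sensible default and is what the pipeline
stage constructs).

AUCell-style scoring: per cell, genes are ranked by expression descending
with seeded random tie-breaking (important for sparse data, where most genes
tie at zero); the score is the area under the gene-set recovery curve within
the top 5% of ranks, normalized by the maximum achievable area, hence in
[0, 1] and invariant to monotone transforms of the cell's expression vector.
Group comparison by a classical pooled-variance two-sample t-test (Welch
behind a flag).

## Annotation (`annotate`)

Cluster profiles are mean CPM over member cells; panels and profiles are
restricted to common genes and CPM-scaled before fitting. The lasso is fit
on internally standardized inputs (both the panel columns and the target
z-scored), so a perfect identity match carries weight ≈ 1 and the 0.1 label
threshold has a scale-free meaning. Note one consequence: for an equal
mixture of two orthogonal equal-variance profiles the standardized weights
are ≈ 0.707 each, not 0.5 — the coefficients are on the standardized scale,
not mixture proportions. Weights are not constrained non-negative (plain
lasso); the penalty is chosen by 5-fold cross-validation over a log grid
when not supplied, and a penalty of exactly 0 falls back to least squares.

## Saturation (`saturation`)

Draws are without replacement from the labeled population (subsampling an
atlas, not resampling); per-type draw counts use the multivariate
hypergeometric distribution, identical in law but O(#types) per draw, which
makes the default 0–50,000-cell grid at 50 repetitions cheap. A type is
detected when at least `threshold` of its cells are drawn; thresholds
{1, 5, 10} are reported side by side by the pipeline stage since the choice
is design-dependent. Draws are independent across sizes by default
("randomly sampled"); a nested mode reuses one permutation per repetition
and is used for the monotonicity property. The Michaelis–Menten fit is
nonlinear least squares initialized at `Vmax = max mean` and `Km = size
nearest half of it`.

## Behavioral and physiology scores (`phenoscores`)

SING: tube-weighted count sum over total×5, in [0.2, 1]. Preference index:
`(n_A − n_B)/total` in [−1, 1]. ΔF/F: `(F − F₀)/F₀` with F₀ either the mean
of the five frames before stimulus onset (evoked, in vivo preset) or the
minimal five-frame rolling mean (spontaneous, culture preset). Activity: a
frame is active when ΔF/F exceeds 2×SD of the declared baseline frames;
the fraction is active/total frames and the amplitude is the trace maximum
over all frames (not only active ones — the distinction is immaterial for a
maximum above threshold). Two caveats are inherent to these definitions: a
2×SD threshold admits ~2.3% of pure Gaussian noise frames regardless of the
noise scale, and the minimal-window F₀ sits below the noise mean, shifting
ΔF/F slightly positive; recovery tests therefore compare ROI-averaged
fractions and prefer the pre-stimulus baseline. Background subtraction is
assumed done upstream. The feeding-dose helper converts a per-ml food
concentration, daily intake in µl and body weight in mg to a per-mg daily
dose (0.2/ml × 1 µl/day ÷ 0.1 mg = 0.002).

## The synthetic-data generator (`synthgen`)

`generate_cohort` emulates: several mutant genotypes plus a control;
log-normal cluster sizes (median 200 cells, σ = 0.4 by default); gene
baseline means log-normal with median 0.5 counts/cell (a sparse brain-tissue
regime that exercises the QC thresholds) modulated per cluster (σ = 0.5 in
log space) so cluster profiles are mutually distinguishable; NB2 counts with
dispersion α = 0.5; round-robin run labels within genotype (guaranteeing
several pseudobulks per contrast when cells suffice); and a mitochondrial
gene subset. Planted effects multiply gene means by `2^(±lfc)` in the
vulnerable clusters of mutant genotypes only; a configurable fraction of
planted genes is shared (same gene, same sign) across all mutants, the rest
are genotype-private. An optional `background_deg` plants mild genotype-wide
deregulation in *every* cluster of a mutant: this gives null clusters a DEG
count that grows with cluster size — the regime the DEG-count model exists
for — and is enabled in the vulnerability-recovery experiments. It defaults
to 0 so that the no-effect limits (uniform null p-values, equal means) hold
exactly at the defaults.

Not emulated: ambient RNA, doublets, UMI saturation, batch effects beyond
run labels, cluster-specific dispersion, or any read-level structure.
Passing recovery tests therefore demonstrates correctness of the estimators
under the model's own assumptions, not robustness to the artifacts real
droplet data carries.

Companion generators: bulk reference panels as cluster means with
multiplicative log-normal noise; orthologue maps with uniform integer scores
and a configurable unmapped fraction; fluorescence traces as baseline +
instantaneous spikes + Gaussian noise with the planted active fraction
recorded. Every generator is byte-deterministic under its seed.

## Pipeline (`pipeline`, `cli`)

Stages run in a fixed order (simulate → qc → de → vuln → converge →
xspecies → annotate → saturate → pheno) from a YAML config with per-stage
parameter blocks; unknown keys and out-of-order stages are rejected before
anything runs, and a dry-run mode validates without touching outputs. The
global seed is expanded into per-stage substreams via `SeedSequence.spawn`,
so stages are reproducible independently. The manifest records per stage the
parameters, seed and SHA256 of every output; identical configs produce
identical manifests.

## Problem sizes in the shipped checks

The test suite and acceptance script run on deliberately desk-scale cohorts:
the concordance experiment uses 20 clusters × ~200 cells per arm × 2000
genes (the published analyses of this design operate on hundreds of
thousands of cells and 186 clusters); recovery experiments use 8–15 clusters
with 250–2000 genes and 50 seeded repetitions where a frequency is asserted.
These sizes were chosen so each property is tested at the smallest scale at
which its statistical claim is meaningful.

## Known limitations

- The pseudobulk NB test does not share dispersion information across genes;
  at 2–3 pseudobulks per arm its power is accordingly low (by design — the
  cross-method concordance, not per-gene agreement, is the contract).
- The hypergeometric overlap p is only as meaningful as the declared
  universe; the package refuses to invent one.
- AUCell tie-breaking is randomized, so per-cell scores on heavily tied data
  carry seed-level jitter (the seed is a parameter).
- `rank_vulnerable` treats genotypes symmetrically; there is no weighting
  for genotypes with more cells or runs.
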