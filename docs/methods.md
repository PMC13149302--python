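# Methods

This note documents the models, estimator choices, defaults and known
limitations of perturbcircuit. It states what each stage assumes and why
the open design choices were resolved the way they were; every number it
mentions is computed by the test suite or `scripts/acceptance.py` at run
time.

## Synthetic screen model

The generator plants a three-level architecture: perturbation → program →
gene.

- **Programs.** `n_programs` (default 17) gene sets partition ~85% of the
  `n_genes` (default 2,000) genes; the remainder (plus the mitochondrial
  genes) form an unregulated background. Most genes belong to a program
  because the clustering stage, like its real counterpart, partitions all
  clustered genes into programs.
- **Regulators.** Each program is shifted by 2–3 of the `n_targets`
  (default 16) target genes, with a random sign and a magnitude drawn
  uniformly from [0.2, 0.6] on the natural-log scale per
  (target, program) pair, times a per-gene jitter in [0.8, 1.2].
  Regulator patterns are kept distinct across programs so programs are
  identifiable from their response profiles; every target regulates at
  least one program.
- **Counts.** A cell carrying perturbation p has expected expression
  μ_g·exp(β_true[p,g])·ℓ_c, with baseline means μ_g ~ LogNormal(0, 1),
  library-size factors ℓ_c ~ LogNormal(0, 0.3), and counts drawn
  negative-binomially with per-gene dispersion φ_g ~ U(0.05, 0.5)
  (var = μ + φμ²), via the gamma–Poisson mixture. Ten mitochondrial genes
  (`MT-*`) carry ~8% of counts with an extra per-cell LogNormal(0, 0.5)
  factor, so the mitochondrial-fraction QC filter has a realistic failure
  tail (~2–3% of cells).
- **Guides.** Each cell's carried guides yield NB(mean 50, φ = 0.05)
  capture UMIs; every guide also has a Poisson(0.05) ambient background, so
  guide calling genuinely has to threshold. Doublets (default rate 0.3,
  matching a screen in which about two-thirds of cells carry a single
  sgRNA) carry two independently drawn guides and the sum of both effects.
- **Cohorts.** Bulk samples have a latent program activity a ~ N(0, 1);
  signature genes read out a plus N(0, 0.3) noise, other genes are
  independent noise. The hazard is h₀·exp(log(HR)·a + covariate effects)
  with h₀ = 0.1, age/cytogenetic-risk/mutation-flag effects of realistic
  sign and size, exponential event times, and independent exponential
  censoring whose rate is set from the target censoring fraction. Drug
  AUC tables plant one drug with exact population correlation r to a
  (AUC = 100 + 20·(r·a + √(1−r²)·ε)) plus independent null drugs.

All randomness flows from one master seed through SHA-256-derived,
label-named child streams (`stream_seed(master, label)`), so stages are
reproducible independently of execution order and all derived seeds stay
below 2³¹.

**What the generator does not emulate:** ambient RNA, batch and cell-cycle
effects, copy-number structure, read-level noise, gene–gene co-expression
within programs beyond the shared perturbation response, and real PPI
topology (edges follow a stochastic block model on the planted programs).
Passing tests therefore demonstrate correct inference under the stated
generative model, not robustness to those artifacts.

## QC and guide assignment

Cells are retained iff detected genes ≥ 200 AND total counts ≥ 1000 AND
mitochondrial fraction ≤ 0.20 — the removal rules are worded as "fewer
than", "below" and "more than", so retention is inclusive at each boundary.
The filter is a conjunction of per-cell predicates and hence
order-independent.

Guide calling: guides with UMIs ≥ `min_umi` (default 3) are candidates; no
candidate → unassigned, one → singlet, several → singlet for the top guide
iff top ≥ `dominance_ratio` (default 2) × runner-up, else doublet. This is
the only reading of a threshold-plus-dominance rule under which two
comparably captured guides yield a doublet. Only singlets enter downstream
stages; sgRNAs are collapsed to their target gene.

## Differential expression

Genes detected in strictly more than 50% of control cells are tested.
The test is a two-sided Wilcoxon rank-sum on log-normalized values —
exact enumeration when both groups have ≤ 8 cells and no ties, otherwise
the tie-corrected normal approximation (scipy) — with
log2FC = log2((mean expm1 + 10⁻⁹)/(mean expm1 + 10⁻⁹)) across groups and
Benjamini–Hochberg adjustment within each perturbation's family
(configurable to a single global family). Genes identical across both
groups get p = 1 and log2FC = 0.

## Regulatory matrix

Normalization is log1p of counts per 10,000. Highly variable genes follow
the binned mean/dispersion convention: mean and variance on the expm1
scale, dispersion = var/mean, log-dispersion z-scored within 20 equal-width
bins of log1p(mean); keep iff 0.0125 ≤ log1p(mean) ≤ 3 and normalized
dispersion ≥ 0.5 (single-bin fallback below 20 usable genes).

The fit minimizes (1/2n)||y − b₀ − I_Δβ||² + λ(α||β||₁ + (1−α)/2·||β||²)
per gene by cyclic coordinate descent with soft-thresholding; the
intercept is unpenalized (handled by centering), so with controls defining
the baseline, b₀ estimates control-mean expression and β is the log-scale
departure per perturbation. α defaults to 0.5. Cells are pre-sorted by
barcode and split 80/10/10 stratified by perturbation from a seeded
permutation, making the result invariant to input order.

Four estimator refinements (all exposed in `FitParams`, each revertible)
make one shared λ meaningful and the selected support trustworthy:

1. **Response standardization.** Each gene's y is z-scaled on the training
   cells and coefficients are back-transformed. Without it a shared λ is a
   harsher threshold for low-expression genes (their coefficients and
   noise are both small in absolute units), which distorts support
   recovery across the expression range.
2. **Adaptive L1 weights** 1/|β_OLS|² (γ = 2). Plain lasso tuned for
   prediction keeps spurious coefficients at roughly a 1.5σ threshold and
   is not selection-consistent; adaptive weighting restores consistent
   support recovery while leaving large effects nearly unpenalized.
3. **BIC λ selection** (pooled over genes on the training fit). BIC tuning
   of adaptive penalties is selection-consistent, where any
   validation-MSE-minimizing rule plateaus before full sparsity.
   Validation and test MSE are still computed on the 80/10/10 split and
   reported (in standardized units); `"min"` and `"1se"` validation rules
   remain available. Test MSE is never used for selection.
4. **Relaxed refit.** The selected support is refit unpenalized per gene,
   so reported effect sizes are not shrunk toward zero.

Convergence is declared when the largest coefficient change in a sweep is
below `tol` (10⁻⁶); non-convergence at `max_iter` (2,000 sweeps) is
flagged and the partial result returned. The objective is non-increasing
across sweeps and the nonzero count is non-increasing in λ (both are
property-tested).

On the default synthetic screen this estimator attains Pearson r ≈ 0.9
between fitted and planted nonzero coefficients while setting ≈ 98% of
truly-zero coefficients exactly to zero (recomputed by
`scripts/acceptance.py`). Note the recovered coefficients estimate the
effect on the log1p-normalized scale, which compresses the planted
log-scale effect by an expression-dependent factor; correlation, sign and
support are preserved, absolute magnitudes are attenuated for
low-expression genes.

## Gene programs

The gene graph connects each gene to its k = 5 nearest neighbors (union of
directed lists, unit weights) by **cosine** distance between coefficient
columns: a program is a shared *direction* of perturbation response, while
each member gene responds with its own magnitude, so Euclidean distance
strings magnitude-ordered genes into chains that community detection then
cuts — it fragments even noise-free block-structured matrices. All-zero
profiles are defined as mutually identical (distance 0) and maximally far
(2) from responsive genes, so unregulated genes form one background
cluster. Euclidean distance remains available. Ties break
lexicographically by gene id (genes are pre-sorted), making the graph
deterministic under input permutation.

Louvain (networkx, seeded, resolution 1.0) is followed by two merge
passes: clusters whose mean coefficient profiles correlate ≥ `corr_merge`
(default 0.8) are agglomerated — kNN-Louvain over-fragments a program when
its genes differ in which weak coefficients survived penalization, and
0.8 exceeds the profile correlation of sibling programs sharing
all-but-one regulator — and clusters below `min_program_size` (default
10) are absorbed by their best-correlated neighbor. Programs are labeled
P-0, P-1, … in decreasing size; labels are data-dependent, so benchmarks
match programs to planted truth by Jaccard overlap rather than by label.

Signatures are the top ceil(0.25·size) member genes by regulatory weight
(mean |β| over the program's top-3 loading perturbations; both the
fraction and the weight rule are configurable), ties broken by gene id.

Per-cell activity is mean signature expression minus bin-matched control
genes: genes are ranked into 24 equal-occupancy bins by mean expression;
each signature gene is compared with up to 100 seeded-sampled
non-signature genes from its bin (widening to neighboring bins when a bin
is signature-dominated). Because the subtraction is paired within each
cell, the score is exactly invariant to adding a constant to all genes of
a cell. A plain z-score mean (`zmean`) is available. Per-perturbation
program enrichment uses Welch's two-sided t-test against control cells
with BH adjustment across all (perturbation × program) pairs; exactly
degenerate equal groups get p = 1.

## Interaction indices

Ω = I + symmetrized off-diagonal PPI scores restricted to the pathway's
gene space (duplicate edges take the maximum; self-edges are ignored with
a warning). Dense score matrices are generally indefinite, so negative
eigenvalues are clipped to zero and the diagonal re-normalized to 1; the
repair magnitude is recorded and logged when it exceeds 10⁻⁶. PSD Ω
guarantees |S| ≤ 1 by Cauchy–Schwarz (numerical overshoot is clipped at
±1).

Target vectors are signed log2 fold changes masked at FDR < 0.05 over the
pathway's genes — the signed form is what lets antagonism (opposite
effects on shared targets) be distinguished from disjointness. A
zero-norm vector makes S undefined for that pair/pathway; it is reported
as missing, never as 0. The aggregate S is the equal-weighted (weights
configurable) mean over defined pathways, and SI = 100·max(0, S),
AI = 100·max(0, −S) — a linear clip anchored at "none at 0, full at 100".
The published scale for these indices is not fully derivable from any
stated formula, so the printed linear mapping is one admissible choice and
index values should be compared within an analysis, not across tools.

## Clinical translation

Bulk scoring is the mean of per-gene z-scored (across samples) signature
expression; constant genes are excluded with a log entry, and a rank-based
percentile mean is available. Cox fits use lifelines (Efron ties, Newton
iteration); covariate adjustment encodes cytogenetic risk as an ordered
categorical with treatment contrasts (favorable baseline) and mutation
flags as 0/1. Separation or non-convergence triggers one
ridge-stabilized retry (penalizer 0.1) with the result flagged.
Kaplan–Meier stratification cuts at the median; the low group includes the
threshold sample, so with odd n the larger group contains the median.

The permutation-specificity null draws size-matched uniform random gene
sets from the candidate pool, scores each (from a pre-standardized
expression matrix, so a draw is a column-mean), and fits an unadjusted
single-covariate Cox model with an in-package Efron Newton solver that is
cross-checked against lifelines and against a brute-force
partial-likelihood grid in the tests. Every score — observed and null —
is scaled to unit variance before its fit, so hazard ratios are per
standard deviation of score and comparable across gene sets whose raw
score variances differ (a 20-gene random-set mean has far smaller variance
than a coherent signature's score; without this the comparison is a scale
artifact). The empirical p uses the add-one estimator
(1 + #{null HR ≤ observed}) / (n + 1); non-converging draws are dropped
and counted. Permutation fits are unadjusted by default (adjusted fits
cost ~50× more and specificity targets the signature, not the
covariates); `perm_adjusted` exists as a config flag on the pipeline
level.

Drug correlation is pairwise-complete Pearson r per drug (≥ 20 pairs),
BH-adjusted across drugs; negative r is labeled sensitizing, following
the convention that lower AUC means higher sensitivity.

## Pipeline, formats, determinism

Counts travel as a CellRanger-style Matrix-Market triplet (feature ×
barcode on disk, 1-based; cell × gene, 0-based in memory), guides and PPI
as TSV, pathways as GMT, cohorts as clinical + expression CSV; all readers
accept gzip. Gene identity is plain case-sensitive symbols with no alias
resolution. The pipeline runner executes
simulate? → qc → assign → de → fit → programs → interact → clinical,
serializes the effective config next to the outputs, and writes a manifest
with a SHA-256 hash per artifact; a rerun with the same config and master
seed reproduces every hash (the config echo records the output path and is
excluded from determinism comparisons). A stage failure still writes the
manifest of completed stages. Editable default fitness pathway sets
(apoptosis, cell cycle, checkpoint) ship as a GMT resource; the simulate
stage writes synthetic counterparts derived from the planted programs.

## Problem sizes in tests and acceptance

The benchmark runs at the full default scale (16×3×182 cells + 500
controls, 2,000 genes; ~20 s). Statistical calibrations use the smallest
sizes at which the check is informative: 1,000 null genes for rank-sum
type-I error; 50 replicates at n = 200 for null CI coverage; 100 runs ×
200 permutations for permutation-p uniformity; n = 500 cohorts for hazard
and drug-correlation recovery; the demo pipeline (8 targets, 800 genes)
for end-to-end determinism. The full suite completes in about a minute on
one CPU.

## Known limitations

- Coefficients are attenuated relative to the planted log-scale effects by
  log1p compression; analyses interpreting absolute effect sizes should
  account for this.
- One shared λ across genes (even standardized and adaptive) is a
  compromise; strongly heteroscedastic real data may favor per-gene
  selection, which the design intentionally avoids to keep one
  interpretable matrix.
- The SI/AI 0–100 mapping is a linear clip of the weighted-mean S; other
  monotone mappings are equally admissible.
- The permutation null is unadjusted; a signature confounded with
  covariates can look specific.
- Louvain is seed-deterministic but not canonical: different seeds can
  yield different (near-equivalent-modularity) partitions.
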