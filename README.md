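# perturbcircuit

Map transcriptional regulatory circuits from pooled CRISPR screens with
single-cell RNA-seq readout (Perturb-seq), and translate the discovered gene
programs into clinical associations. The package is aimed at computational
biologists analyzing screens in which each cell carries a barcoded sgRNA
naming its perturbed gene — for example epigenetic-regulator knockouts in an
acute myeloid leukemia cell line — and who want a tested, reproducible path
from a raw count matrix to regulatory effects, gene programs, perturbation
interactions, and cohort-level survival and drug-sensitivity readouts.

## What it computes

**Regulatory matrix.** Each highly variable gene's log-normalized expression
y is regressed on the binary perturbation indicator matrix I<sub>Δ</sub>
(non-targeting control cells have all-zero rows) with an elastic-net
penalty,

    min over β of  ||y − I_Δ·β||² + λ(α||β||₁ + (1−α)||β||²₂)

giving a perturbation × gene coefficient matrix β of log-scale expression
shifts. Cells are split 80/10/10 into training/validation/test sets; one λ
is shared by all genes. By default the package fits the adaptive variant
(L1 weights 1/|β<sub>OLS</sub>|², per-gene response standardization, BIC-selected λ,
unpenalized refit on the selected support), which recovers the true support
of a sparse β consistently; the plain estimator and validation-MSE λ rules
remain available through configuration.

**Gene programs.** Genes are clustered on their columns of β with a
k-nearest-neighbor graph (k = 5) and Louvain community detection; a
program's *signature* is its top 25% of genes by regulatory weight, and
program *activity* is scored per cell (mean signature expression minus
bin-matched control genes) or per bulk sample (mean z-score).

**Interaction indices.** Two perturbations' significant effects a, b on a
fitness pathway (apoptosis, cell cycle, checkpoint) are compared under a
protein–protein-interaction-weighted inner product ⟨a,b⟩<sub>Ω</sub> = aᵀΩb,

    S(a,b) = ⟨a,b⟩_Ω / sqrt(⟨a,a⟩_Ω · ⟨b,b⟩_Ω),

with Ω built from a PPI edge list (unit diagonal, repaired to positive
semidefinite so |S| ≤ 1). The pathway-averaged S maps onto a Synergistic
Index SI = 100·max(0, S) and an Antagonistic Index AI = 100·max(0, −S).

**Clinical translation.** A program signature is scored in bulk cohorts and
associated with overall survival by Cox proportional-hazards regression
(Efron ties; optional adjustment for age, cytogenetic risk and
FLT3/NPM1/TP53/DNMT3A/CEBPA/RUNX1 mutations), visualized by Kaplan–Meier
stratification with a log-rank test, checked for specificity against
thousands of size-matched random gene sets, and correlated with drug
response (Pearson r against AUC; lower AUC = higher sensitivity).

**Synthetic data.** A ground-truthed generator produces every input the
pipeline consumes — negative-binomial UMI counts with planted
perturbation→program effects, guide-capture tables, PPI edges, pathway
sets, survival cohorts with a planted hazard ratio, and drug-response
tables with a planted correlation — so the full analysis is testable
offline against known truth.

## Worked example

Run the shipped fully-simulated demo (8 targets × 3 sgRNAs, 800 genes, 6
planted programs, a 500-sample cohort with a planted hazard ratio of 0.5):

```bash
perturbcircuit run --demo --out demo_out --seed 0
```

This executes simulate → QC → guide assignment → differential expression →
regulatory matrix → programs → interaction → clinical, writing every
artifact plus a content-hashed `manifest.json` under `demo_out/`. With seed
0 it reports 7 gene programs (6 planted + the unperturbed background
cluster) at a selected λ of 0.00522, and `outputs/clinical.json` contains

```json
"cox_adjusted": {"hazard_ratio": 0.523, "ci95": [0.392, 0.698], "p": 1.04e-05},
"km_logrank_p": 0.0040,
"top_sensitizing_drug": {"drug": "DRUG_TARGETED", "pearson_r": -0.114}
```

— the covariate-adjusted hazard ratio per unit of program score recovers
the planted protective effect (0.5), patients stratified by median program
score separate in the Kaplan–Meier analysis, and the drug planted to
correlate with program activity is ranked as the top sensitizing agent.
Rerunning the same command reproduces every output hash bit-for-bit.

The same stages are available as a library:

```python
import perturbcircuit as pc

res = pc.run_screen(seed=1)          # simulate + QC + assign + fit + cluster
metrics = pc.recovery_metrics(res)   # compare against the planted truth
```

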