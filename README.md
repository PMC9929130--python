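# metaniche

Analysis pipeline for dissecting the cellular ecosystem of metastatic tumors
from single-cell RNA sequencing: quality control, clustering and marker-based
cell-type annotation; expression-derived copy-number inference with subclone
and clonality-tree reconstruction; discovery of recurrent expression programs
with program-cell scoring and co-occurrence statistics; permutation-based
ligand–receptor interaction testing; and gene-signature / cell-cycle / entropy
scoring. A synthetic-cohort generator plants known ground truth (cell types,
CNV subclones, activity programs, ligand–receptor effects) so every stage can
be validated against a recoverable answer.

The package is written for computational biologists analysing tumor
microenvironments — in particular multi-sample cohorts from two organ
contexts (e.g. liver and brain metastases) — who want each bespoke step of
such a study as a tested, reusable function rather than a one-off notebook.

## Methods at a glance

**QC.** Cells are removed when the detected gene count is < 200, when they
fall in the top 2% of cells by gene count or by UMI count (per sample, a
doublet surrogate), or when > 50% of UMIs are mitochondrial. Expression is
normalized to 10,000 counts per cell and log1p-transformed; clustering is
PCA → kNN graph → Leiden at resolution 1.2; markers are one-vs-rest Wilcoxon
rank-sum tests kept when detected in > 10% of the cluster with ln-fold-change
> 0.25 (Benjamini–Hochberg adjusted).

**Copy-number inference.** For genes detected in > 20 cells, ordered along
chromosomes: per-gene mean-centering, clipping at ±1.5 cross-cell SD, a
101-gene running mean per chromosome (windows truncate symmetrically at
chromosome ends), optional per-cell median centering, and subtraction of the
mean profile of reference T/B lymphocytes. Per-cell CNV burden is
`log1p(mean(dev²))`; a cell is malignant when its score **and** its Ward-linkage
CNV cluster's mean score exceed the 99th percentile of reference scores.
Contiguous deviant runs (≥ 30 genes beyond ±0.15) per subclone become gain/loss
events, *canonical* when carried by > 90% of the subclone's cells, and event
sets are nested by carrier-set inclusion into a clonality tree with truncal
events at the root.

**Recurrent expression programs.** Malignant cells are subclustered within
each sample; each subcluster yields a module (top-100 marker signature,
bin-matched control score over all malignant cells). Modules are meta-clustered
by Pearson correlation of score vectors (average linkage, cut r = 0.3);
programs whose members span ≥ 2 samples are *recurrent*. A cell is a *program
cell* when it expresses strictly more than 70% of the program's consensus
genes; the per-sample *program score* is the exact proportion of program
cells. Pairwise program dependencies use the Haldane–Anscombe corrected log
odds ratio ln((a+½)(d+½)/((b+½)(c+½))), classified co-occurring (> 0.1) or
mutually exclusive (< −0.1).

**Ligand–receptor testing.** For a pair (L, R) and ordered types (s, r), the
statistic is (mean L in s + mean R in r)/2 on log-normalized expression; the
null comes from 1000 permutations of the type labels with the add-one
estimator p = (1 + #{null ≥ obs})/(n_perm + 1). A result is significant when
the statistic exceeds 0.1 and p < 0.05.

**Signatures.** Module scores subtract bin-matched control genes (expected 0
for a random set). Cycle phases follow the two-score rule (G1 = noncycling
when neither S nor G2M score is positive). Stemness is summarized by Shannon
entropy of the cell's expression profile (ribosomal/spike-in genes excluded)
with a gene-bootstrap SD.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohort (4,200 cells × 2,000 genes, six samples, three planted CNV
segments, three planted programs, one planted myeloid→cancer ligand–receptor
pair):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_and_annotate.py
python analysis/03_cnv_subclones.py
python analysis/04_expression_programs.py
python analysis/05_cell_interactions.py
python analysis/06_signatures_and_cycling.py
```

Selected output (abridged):

```
QC kept 4091/4200 cells (76 top-gene, 78 top-UMI)
clustering at resolution 1.2: 11 clusters
cell-type annotation accuracy vs truth: 0.996

malignancy calls: 1701 of 4091 cells (sensitivity 0.981, specificity 1.000 vs truth)
clonality tree: 2 subclones; trunk events: ['chr1:15-161:gain', ...]
  HCL1 (879 cells): [('chr2:407-555:loss', 100.0, True)]
  HCL2 (822 cells): [('chr3:627-765:gain', 100.0, True)]

planted myeloid->cancer pair: stat 2.82, p 0.000999, significant=True

checkpoint receptor means in T cells:
  LAG3: mean 2.28 ... PDCD1: mean 1.38
LAG3/TIGIT/CD96/KLRB1 all above PDCD1 in T cells: True
```

Reading the numbers: QC removed exactly the per-sample top-2% tails (no cell
fell below 200 genes at this depth); the planted truncal fold-2 gain appears
as a canonical (>90%) trunk event with one private canonical event per
subclone; the planted ligand–receptor pair reaches the minimum attainable
permutation p-value 1/1001; and the planted checkpoint asymmetry (inhibitory
receptors high, PD-1 at baseline) is recovered in the dot-plot statistics.

A thin CLI wraps the same functions (`metaniche simulate|preprocess|cnv|
programs|interact|score`); see `metaniche --help`.

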