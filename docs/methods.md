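# Methods

This note documents the models and procedures implemented in `metaniche`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Synthetic cohort model

`metaniche.sim` draws a cells × genes count matrix from a hierarchical model:

- **Gene baselines.** Per-gene negative-binomial means are
  `baseline_mean · LogNormal(0, gene_mean_sigma)` with `baseline_mean = 5.0`
  and `gene_mean_sigma = 0.6`. With the default 2,000-gene panel this yields
  roughly 10⁴ UMIs and ~1,400 detected genes per cell, matching the depth of a
  typical 10x tumor cohort (≈2,400 genes / ≈9,800 UMIs per cell) at panel
  scale.
- **Counts.** `NB(mean = μ_cg, dispersion = 0.5)` where
  μ_cg = baseline_g · lib_c · marker · CNV · program · LR effects, with
  `lib_c ~ LogNormal(0, 0.25)` (library size) followed by independent
  Bernoulli dropout at rate 0.10.
- **Design.** Six samples split liver/brain, six cell types with a
  cancer-dominant composition (300 cancer + 400 non-cancer cells per sample);
  each type gets 10 marker genes at fold 8 (or user-specified markers).
- **CNV.** A segment multiplies the NB mean of its genes (dosage effect on
  expression, which is all an expression-based caller can see) in carrier
  cells; segments carry a subclone id (`None` = truncal) and a carrier
  fraction. Gene "positions" are 0-based indices along synthetic chromosomes —
  only ordering matters for the windowing.
- **Programs.** A program multiplies its gene set's means by
  `activation_fold` in a per-sample fraction of malignant cells; pairwise
  dependencies are planted by re-drawing joint activity with exact marginals
  (`cooccur` = maximal overlap, `exclude` = minimal, `independent` = product).
- **Ligand–receptor.** The ligand's mean is raised `effect_fold`-fold in the
  sender type and the receptor's in the receiver type.

Identical configs (including seed) are bit-identical. Ground truth (cell type,
malignancy, subclone, program activity) is a sidecar table keyed by barcode.

**What the generator does not emulate:** batch effects, ambient RNA, doublets,
UMI-level noise, gene-length or GC biases, realistic gene–gene correlation
beyond the planted effects, and organ-specific expression differences beyond
the sample labels. Passing tests therefore establish correctness of the
procedures under NB noise with library-size variation and dropout — not
robustness to every artifact of real tissue data.

## QC, normalization, clustering, markers

- The four QC rules are literal: `n_genes < 200`; top 2% by `n_genes`; top 2%
  by `n_umis`; mitochondrial fraction > 0.5. The top-fraction rules use the
  `(1 − f)` quantile (method "higher") computed per sample — the per-sample
  choice treats each library's depth distribution separately and is
  configurable. Cutoffs can be supplied from a reference matrix, which makes
  repeated filtering idempotent; the boundary semantics are strict (`= 200`
  genes and `= 50%` mito survive).
- Normalization is 10,000-count scaling + natural log1p. The dialect is fixed
  here because rank-based downstream tests only need a monotone per-cell
  transform.
- Clustering is PCA (arpack, seeded) → kNN → Leiden with the
  RB-configuration objective at resolution 1.2. Any seeded modularity-style
  community detector would satisfy the same contracts.
- Markers: one-vs-rest two-sided Wilcoxon rank-sum per gene;
  logFC = ln((mean expm1 + 1e-9)_in / (mean expm1 + 1e-9)_out); rows kept when
  `pct_in > 0.10` **and** `logFC > 0.25`; BH adjustment across the retained
  table. Clusters of one cell are skipped.
- Annotation assigns each cluster the type whose marker list has the highest
  mean z-scored expression; exact ties go to the lexicographically first type
  and are flagged; clusters with no marker expression are `unassigned`.

## Copy-number inference

Pipeline on log-normalized expression: (1) drop genes detected in ≤ 20 cells;
(2) order genes by (chromosome, position); (3) per-gene mean-centering;
(4) clip at ±1.5 per-gene SD ("ceiling" read as a symmetric bound);
(5) 101-gene running mean per chromosome, truncating the window symmetrically
at chromosome ends (the largest centered window ≤ the chromosome's gene count;
no edge NAs); (6) subtract the mean reference (T/B cell) profile. The result
is a deviation matrix with 0 = neutral.

- **Per-cell median centering** (`center_cells=True`, step 5b) subtracts each
  cell's median smoothed value before the reference is removed. Sequencing
  depth and dropout shift a cell's whole profile; without this step the global
  offset dominates the squared-deviation score and large planted segments also
  deflate the rest of the genome through library normalization. The option is
  off by default — the plain six-step pipeline is the documented contract and
  keeps a constant planted offset visible — and on in the malignancy/event
  pipelines, where it is the recommended setting.
- **Score and malignancy rule.** `score = log1p(mean(dev²))`; malignant iff
  the cell's score and its CNV cluster's mean score both exceed
  `Q(reference scores, 0.99)`. Both the formula and the rule are fixed here
  (no published closed form exists for either) and are configurable.
- **Events.** Per subclone, contiguous runs of ≥ 30 genes with mean deviation
  beyond ±0.15 become events; `cell_percent` is the percentage of subclone
  cells whose own span mean passes half the threshold; canonical ⇔ > 90%.
  The ±0.15 / 30-gene defaults were calibrated on synthetic planted segments.
- **Tree.** Events are matched across subclones by chromosome, direction and
  span overlap; matched keys are nested greedily by carrier-set inclusion
  (all-subclone events = trunk). Carrier sets violating nesting attach at the
  deepest compatible node and are flagged, never fatal. Leaves are the
  subclones; leaf cell counts sum to the malignant cell count.
- **Known confound:** an expression program active in a localized gene block
  is indistinguishable from a dosage change — in the default cohort the
  planted programs surface as a short extra trunk event. This is inherent to
  expression-only CNV inference, not an implementation artifact.

## Recurrent expression programs

Per sample, malignant cells are subclustered (Leiden, resolution 1.0, seeded)
and each subcluster becomes a module: signature = its top-100 genes by marker
logFC (a single-subcluster sample falls back to its top expressed genes;
signatures under 10 genes are dropped as uninformative), score = bin-matched
control score over **all** malignant cells so modules are comparable across
samples. Module extraction via subclustering (rather than a matrix
factorization) is the design choice here; the scoring and aggregation steps
are factorization-agnostic, so an NMF extractor could be slotted in without
touching the rest.

Aggregation: Pearson correlation of module score vectors → distance 1 − r →
average linkage → cut at r = 0.3 (configurable; chosen so that modules sharing
roughly a third of their variance merge). Consensus genes = genes in > 50% of
member signatures, topped up by membership frequency to a 10-gene minimum.
Programs are *recurrent* when their members span ≥ 2 samples; single-sample
programs are retained but flagged, and the recurrent subset is what the
analysis reports — recurrence across samples is the defining property of a
shared program, and on synthetic cohorts it cleanly separates planted programs
from per-sample noise modules.

Program cells: "expressing" a gene means normalized value > 0, and the > 70%
rule is strict (7/10 genes is not a program cell). Note that at the default
simulated depth most genes are detected in most cells, so program-cell calls
are permissive there; the rule discriminates sharply only at realistic
whole-transcriptome sparsity. Program scores are exact integer ratios per
sample. Dependencies: Haldane–Anscombe corrected log OR with ±0.1 class
thresholds ("odds ratios > 0.1 / < −0.1" can only be a log-scale statement,
since raw odds ratios are nonnegative); the matrix is exactly symmetric and
negating one indicator exactly negates the pair's value.

## Ligand–receptor permutation test

All ordered (sender, receiver) pairs of types with ≥ 10 cells are tested for
each database pair, provided the ligand is detected in > 10% of sender cells
and the receptor in > 10% of receiver cells (the detection threshold is a
documented default; only its existence, not its value, is standard). The
statistic is the arithmetic mean of the two type means (a `min` variant is
available); the null permutes type labels over all cells, 1000 times by
default; p-values use the add-one estimator, so p ≥ 1/1001 and no p-value is
zero. Significance = statistic > 0.1 and p < 0.05. The test is calibrated
under a clean null; on cohorts with large CNVs even unplanted genes carry mild
type signal through library renormalization, which inflates nominal positives
— a property of label-permutation tests on heterogeneous data generally.

## Signature scoring, cycling, entropy

- **Module score:** mean expression of the set minus the mean of control genes
  drawn per set gene (100 draws, with replacement) from the same
  average-expression bin (25 bins); expectation 0 for a random set; exactly 0
  when a set is forced to be its own control. Scores scale linearly with the
  data.
- **Phases:** G1 when `max(S, G2M) ≤ 0` (noncycling), otherwise the larger
  score's phase; exact positive ties go to S and are flagged. In a mixed
  population the bin-matched controls make quiescent cells genuinely negative
  on cycle sets, which is why the two-score rule works.
- **Entropy:** with p_g = expression_g / Σ expression, entropy = −Σ p_g ln p_g
  over p_g > 0, after removing RPL/RPS/ERCC-prefixed genes; bounds 0 ≤ H ≤
  ln(G); uniform-over-k profiles give exactly ln k; bootstrap SD comes from
  resampling genes with replacement (100 draws). This is a profile-entropy
  stemness summary with a bootstrap, not a reimplementation of any specific
  published entropy pipeline.
- **Dot-plot statistics** report, per (cluster, gene), the mean expression,
  its z-score across clusters, the expressing fraction, and a within-cluster
  mean rank so statements like "receptor A exceeds receptor B in cluster X"
  are machine-checkable.

## Numerical conventions

- SDs for clipping use the population convention (ddof = 0).
- The windowed running mean is computed with cumulative sums; an independent
  per-window slice implementation agrees to < 1e-10 and is kept as the
  reference in the test suite and acceptance battery.
- Ward linkage on Euclidean distances (scipy) for CNV clusters — fully
  deterministic; Leiden is seeded everywhere it is used.
- All randomness flows from `numpy.random.default_rng(seed)`; sub-seeds are
  derived arithmetically, never from Python's `hash`.

## Problem sizes

The acceptance battery uses cohorts of 300–2,000 cells and 400–2,000 genes:
five seeds for CNV/tree recovery, ten for program recovery and dependency
classification, 1000 permutations for the interaction test, and one full
default cohort (4,200 cells) end-to-end. These sizes keep the full battery at
a few minutes on one CPU while leaving every planted effect at its stated
strength (fold-2 segments of ≥ 100 genes, fold-3 programs in 40% of cells,
fold-5 ligand–receptor effects).

## Limitations

- Expression-based CNV inference cannot distinguish dosage from coordinated
  transcriptional programs over contiguous gene blocks (see above).
- The malignancy rule assumes the reference cells are genuinely diploid and
  sufficiently numerous for a stable 99th percentile.
- The clonality tree is a greedy laminar construction, not a maximum-likelihood
  phylogeny; conflicting carrier sets are flagged rather than resolved.
- Receptor complexes (multi-subunit) are out of scope for the interaction
  test; database rows are simple gene pairs.
- Program-cell calls saturate on deeply-detected panels (see above); with
  whole-transcriptome sparsity the > 70% rule is discriminative.
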