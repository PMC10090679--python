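# Methods

This note documents the models, rules, and numerical choices behind
`esostrata`, and what the synthetic benchmarks do and do not establish.

## Quality control

Genes expressed (nonzero) in 3 or fewer cells are removed
(`min_cells_per_gene = 4`). Cells are kept when their unique-gene count lies
in [250, 3500] **and** their total UMI count in [100, 9500]; "under X / over
Y" is read strictly, so the bounds themselves are retained. Doublets and dead
cells are handled by these bounds alone — there is no model-based doublet
detector. A cell failing both rules is tallied under the gene-count rule in
the QC report. Equalized downsampling then samples uniformly without
replacement to 1,500 cells per condition (4,500 total for three conditions);
retained count vectors are untouched. If a condition is smaller than the cap
this is an error unless `cap_to_min` is set, which lowers the cap to the
smallest condition.

Order of operations: gene filter → cell filter → downsample → gene re-filter.
The final pass removes genes stranded below the expression threshold by cell
removal; a second application of either filter on its own output is a no-op.

## Normalization

`value = log10(1 + count × median_total / cell_total)`. Zeros map to zero and
all values are nonnegative. The median-total size factor removes per-cell
depth differences: two cells with proportional count vectors receive
identical rows. Because the target depth is the *median* of the data,
rescaling the whole dataset rescales the pre-log values with it (the exact
2× homogeneity is covered by a test); what the classifier consumes —
relative, per-cell depth-corrected expression — is invariant. All marker
means, dot-plot statistics, phase scores and module scores use this one
definition. Cells with zero total counts are left as zero rows with a
warning.

## Batch/replicate regression

A per-gene level-mean removal: within each covariate level the gene mean is
subtracted and the global gene mean added back, equalizing level means
exactly (the linear-model solution for a categorical covariate). The
regressed matrix feeds PCA/UMAP/clustering only; marker and module means are
always computed on the unregressed normalized matrix, so classification is
never distorted by the correction. A single covariate level makes the
transform the identity.

## Embedding and clustering

Genes are centered and scaled to unit variance before PCA (zero-variance
genes are only centered). The top 50 components are taken with a fixed sign
convention (largest-magnitude loading positive). UMAP embeds the scores into
2 components (`n_neighbors = 15`, `min_dist = 0.1`, seeded, hence
deterministic). Clustering is Leiden under the CPM objective at resolution
3 × 10⁻³ on an unweighted symmetric k = 20 kNN graph built in UMAP space —
the convention of trajectory toolkits that cluster in the embedding — with
PCA-space clustering available behind `cluster_space = "pca"`. Labels are
relabeled in order of descending cluster size.

On the default synthetic design (4,500 cells × 2,000 genes after QC) this
recovers the 13 planted populations with ARI ≥ 0.8 in at least 9 of 10 seeds;
occasional seeds split one population into two, which the strip classifier
then assigns to the same stratum.

## Strip classification

For each cluster, x̄ = mean normalized log₁₀ Krt5 and ȳ = mean normalized
log₁₀ Krtdap over all its cells (all-cell means, not per-replicate means).
With d = ȳ − slope·x̄ (slope fixed at 1): |d| ≤ 0.3 → suprabasal;
d < −0.3 → basal; d > 0.3 → superficial. Boundary points belong to the strip.
The rule is symmetric — swapping the two markers swaps basal and superficial
and fixes suprabasal — so the choice of which marker sits on which axis does
not change the biology of the call. Dot-plot summaries report, per marker
gene, the z-score of cluster-average expression across clusters and the
fraction of cells with nonzero expression; the default panel (Krt5, Trp63,
Krt14 / Krtdap, Krt13, Krt4) is a conventional esophageal marker set and is
user-replaceable.

## Cell-cycle scoring and phase calls

The standard module score: all genes are ranked by dataset-average expression
and cut into 25 equal-frequency bins; each phase gene draws 50 control genes
(with replacement) from its bin; the score is the mean expression of the
phase set minus the mean of the pooled controls, per cell. Phase = the larger
positive score (exact ties go to S — an arbitrary, uniformly applied
convention); G1/G0 when both scores are ≤ 0. The shipped S and G2M lists are
murine orthologs of the standard cell-cycle marker sets, as editable text
files.

In cells with the program off, the score's expectation is only slightly
negative (the controls are matched to a dataset average inflated by the
cycling cells), so per-cell G1/G0 calls are noisy — exactly as with the
original method — while population-level majorities and the recall of truly
cycling populations (≥ 90% at the planted 4× up-regulation) are stable.

## Pseudotime root and trajectory

Root rule: among basal clusters whose modal phase is G1/G0, pick the one with
the most kNN edges to the most S-enriched basal cluster; ties break by higher
G1/G0 fraction, then lowest cluster id. The adjacency is read off the
**PCA-space** kNN graph: 2-D layout distances are not faithful to expression
neighborhoods, and the quiescent→S-phase adjacency the rule encodes is an
expression-space property. A manual `--root` override skips the rule.

The trajectory backbone is a minimum spanning tree over cluster centroids in
UMAP space — a deterministic stand-in for a learned principal graph that is
sufficient for root/branch/leaf analysis at this scale. A cell's pseudotime
is the tree geodesic from the root centroid to its cluster centroid plus its
offset projected on the incident edge (for root-cluster cells, the edge
toward the nearest child), clipped at zero and anchored so the root cluster's
minimum is exactly 0. Centroid pseudotime is therefore additive and monotone
along every root-to-leaf path. The terminal-fate report gives, per tree leaf,
each condition's fraction of cells in that cluster and flags leaves where one
condition exceeds every other by 2× (configurable).

## Gene modules

Genes are z-scored across cells (so magnitude does not dominate
co-expression), embedded by UMAP with cells as features
(`n_neighbors = 30`), and partitioned by Leiden (modularity, resolution 0.5)
on a k = 15 kNN graph of the gene embedding. Communities smaller than
`min_module_size = 10` are merged into the nearest larger module by centroid
distance; module ids are ordered by size. On the default pipeline input this
yields on the order of twenty modules; the count is data-dependent and not a
target. Module scores are the per-cluster means of module-gene cluster means,
z-scaled across clusters within each module (population σ), making rows
comparable. Over-representation of a module in user gene sets is the
one-sided hypergeometric tail with BH adjustment across sets — a generic,
open replacement for proprietary pathway analysis, whose scores are not
comparable to any knowledge-base product.

## Differential abundance

Each replicate contributes one composition vector (its cells' fractions
across clusters; rows sum to 1). For a contrast (case vs control), each
cluster is tested on per-replicate proportions with the **exact two-sided
Mann–Whitney rank-sum test**. The in vivo figure legend names a Wilcoxon
signed-rank test, but the groups are unpaired and of unequal size (3 EoE vs
6 control mice), so a paired signed-rank statistic is not computable; the
rank-sum test is the unpaired member of the same family and is what the data
admit. p-values are BH-adjusted (Bonferroni selectable) across clusters
within a contrast; a cluster is enriched/depleted iff adjusted p < α (0.05)
with direction from the sign of the median difference. All-tied proportions
give p = 1. Note the granularity: with 3 vs 6 replicates the smallest
attainable two-sided exact p is 2/84 ≈ 0.024, so calibration is conservative
(measured type-I ≈ 0.03–0.04 at nominal 0.05) and compositional closure makes
strong planted shifts in a few populations echo through the remaining
proportions.

## Tumor-burden statistics

Tumor load = tumor count × **total** tumor area (mm²) per mouse; the
count × mean-area variant sits behind a flag. Incidence (tumor-bearing
fraction) between groups uses a two-sided Fisher exact test computed by full
hypergeometric enumeration, summing the probabilities of all tables with
probability ≤ the observed one (the enumeration's probabilities are asserted
to sum to 1). Lesion-grade spectra use the same probability-mass criterion on
R×C tables, enumerated exactly when the margin-bound support is ≤ 10⁶ tables
and otherwise estimated by margin-conditional Monte-Carlo permutation
(20,000 draws, seeded, add-one estimator). Group loads and percent neoplastic
epithelium use the unpaired equal-variance Student t-test; two zero-variance
samples with equal means give t = 0, p = 1. Grades are displayed in the order
none < IEN < early ESCC < invasive ESCC, but the test itself is unordered.

## The synthetic-data generator

Counts are negative-binomial via the Gamma–Poisson mixture with shared
dispersion θ = 2 around per-population gene means, scaled to a common target
depth of 2,500 UMI/cell — a splatter-like model without an extra dropout
layer (NB zeros carry the sparsity). The study design is 6 control, 3 EoE
and 4 ESCC replicates at 700 cells each; 2,000 genes.

Planted structure:

* **Populations and markers.** 13 populations: B1–B5 (basal, Krt5 mean 25 vs
  Krtdap 0.6 plus a basal panel), SB1–SB6 (suprabasal, both markers near 8
  within a ×1.2 ratio, inside the strip), S1–S2 (superficial, reversed
  dominance). Each population additionally up-regulates 20 private signature
  genes 4×.
* **Cell cycle.** B2 carries the S program and B3 the G2M program — 4×
  up-regulation of 20-gene sets whose baseline (0.8× the typical gene) is low
  outside the cycling populations, as real phase markers are. B1 carries a
  half-strength copy of B2's signature, planting the quiescent-next-to-
  cycling adjacency that the root rule looks for.
* **Modules.** Four 50-gene blocks whose means are multiplied by a shared
  per-cell lognormal latent factor (σ = 0.8), inducing positive within-block
  correlation; blocks are additionally up-regulated 3× in designated
  populations (an EoE-enriched suprabasal, an ESCC-enriched basal, …). A
  separate Gaussian block generator with exact within-block correlation
  serves the module-recovery benchmarks.
* **Condition effects.** EoE multiplies SB2–SB5 by 3 and B1–B2 by 0.3;
  ESCC multiplies B1, B5, SB6 by 3 and SB1, SB4 by 0.3; weights renormalize
  to 1. The directions follow the reported remodeling patterns; the fold
  changes themselves are unreported anywhere and are chosen here once for
  detectability at this study size — they are synthetic conventions, not
  measured effects.
* **QC noise.** 5% debris cells (means scaled by 0.02: totals ≈ 50, well
  under the 100-UMI bound) and 5% doublets. A literal sum of two typical
  cells (≈ 5,000 UMI) would pass the 9,500-UMI bound, so doublet constituents
  are drawn at 2.2× depth, putting the summed profile above the bound — the
  generator's contract is that qc-noise cells violate the filters.
* **Tumor studies.** Groups of 6/4/10/5 mice. Carcinogen-exposed mice draw
  tumor counts ~ Poisson(6) and per-tumor areas ~ Gamma(2, 0.4) mm²;
  carcinogen-free mice have exactly zero tumors. EoE exposure multiplies the
  Poisson rate by the effect factor (0.3), which lowers both load
  (supra-linearly, since load = count × total area) and incidence
  (Poisson(1.8) leaves ≈ 17% of mice tumor-free, reproducing the ~100% vs
  ~80% incidence split); invasive carcinoma has probability zero in the
  combination group. Percent neoplastic epithelium is Gamma-distributed with
  group-specific means (≈ 31% vs ≈ 12%).

What passing on this generator shows — and does not. The benchmarks establish
that each stage recovers the structure it is designed to detect at realistic
depth and sparsity, that the statistics are calibrated under the null, and
that the full pipeline is deterministic under a fixed seed. They do not
establish performance on real tissue: the generator has no ambient RNA, no
batch chemistry effects, no continuous differentiation gradient between
populations (populations are discrete), and its dispersion is shared across
genes. Results on real data will degrade in proportion to how far those
assumptions are violated.

## Determinism and problem sizes

All randomness flows from one integer seed, expanded per stage
(`PipelineConfig.stage_seed`) so a stage rerun with the same global seed
reproduces bit-exactly; derived seeds are logged and kept below 2³¹. Tables
are written as UTF-8 CSV with floats at 6 significant digits, so identical
(config, counts, seed) runs produce byte-identical outputs.

Default benchmark sizes, chosen as the package's working scale: the full
pipeline runs on the 4,500-cell × 2,000-gene post-QC dataset; clustering
recovery is measured over 10 generator seeds; abundance calibration uses
2,000 null cluster contrasts and 500 effect simulations on multinomial
composition draws (expression draws would add nothing to a proportion test);
module recovery uses 10 seeds of the 200-cell Gaussian block design; tumor
statistics aggregate 200 simulated studies.
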