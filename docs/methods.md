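# Methods

This note documents the models, parameter choices, and numerical decisions
behind `gliongs`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Expression model and preprocessing

Matrices are dense genes x cells frames tagged with a protocol
(`TPM-full-length` for Smart-seq-style data, `UMI-droplet` for 10X/Drop-seq)
and a layer (`raw`/`normalized`). Full-length TPM is log-transformed as
`E = log2(TPM/10 + 1)`; the divisor 10 reflects that full-length TPM
overstates molecule counts roughly tenfold per cell. UMI counts are
library-size normalized to `ln(count/total x 1e4 + 1)`.

The cell filter removes a cell when its detected-gene count is below 3,000
**and** its total signal below 4,000. The conjunction is a deliberate
reading of a removal rule that couples both thresholds; it retains more
cells than the disjunction, and `filter_logic="or"` is exposed for
sensitivity analysis. nCount is computed before mitochondrial-gene removal
(the conventional order). Mitochondrial genes are matched case-insensitively
on the `MT-` prefix so mouse `mt-` naming is covered. No batch correction is
performed anywhere: inter-sample heterogeneity is treated as signal in
gliomas, not noise.

## Clustering and annotation

Highly variable genes: a lowess trend (frac 0.3) of log10 variance on log10
mean predicts each gene's expected variance; genes are ranked by the
variance of their z-scores clipped at sqrt(n_cells). This reproduces the
intent of vst selection without binding to one library's internals.
PCA uses per-gene z-scores clipped at ±10 and a full SVD, so the embedding
is deterministic. The SNN graph uses k = 20 neighbours (including self),
Jaccard edge weights pruned below 1/15, and Louvain modularity optimization
(igraph) with the RNG seeded from the call; cluster ids are relabelled
densely by decreasing size for stability. Default resolution is 0.4.

DEGs use the two-sided Wilcoxon rank-sum test per gene (exact distribution
at small tie-free samples, normal approximation otherwise), BH-adjusted
within each group comparison. logFC is defined as mean log-expression in
the group minus mean outside — log-fold-change definitions vary across
toolkits and versions, so one definition is fixed and documented; the 0.5
threshold applies to this definition. Cluster annotation is a
hypergeometric over-representation test of cluster DEGs in each cell
type's markers, with the DE-tested genes as the universe and BH across all
(cluster, type) pairs; ties break by smaller p then lexicographic type
name.

The binary score of a DEG in a cluster is `f_in x (1 - f_out)` on
detection fractions (expression > 0). It is 1 for a perfectly exclusive
marker, at most 0.25 for a uniformly detected gene, and genes above 0.7
become binary markers. The exact formula of the originally cited score is
not public in this form; this product is the simplest [0,1] exclusivity
score with the required endpoints, and is declared as such. Cells are
(re)assigned to normal clusters when the module score of a cluster's
binary markers exceeds a dataset-specific cutoff (default 0.25, exposed,
since no universal value exists).

## CNA inference

Genes with `Ea = log2(mean TPM + 1) > 4` (strict) are kept; for UMI data,
counts-per-10k stand in for TPM on the same scale. Relative expression is
per-gene centred `E`; the CNA value is its mean over the gene and its 50
genomic neighbours on each side. Windows never cross chromosome
boundaries, and at chromosome ends the divisor is the actual window length
— interior genes use exactly 101. The baseline is the mean CNA of
reference (normal) cells; the CNA signal is the mean squared
baseline-subtracted value over all kept genes, and the CNA correlation is
the Pearson correlation with the mean profile of non-reference cells of
the same sample, excluding the cell itself (leave-one-out avoids
self-correlation inflation; configurable). A dataset with no reference
cells cannot be scored and the CNA criterion is marked not-applicable.
Malignancy evidence requires signal > 0.02 and correlation > 0.4, both
strict.

## Malignancy and NGS classification

The module score bins genes into 30 equal-frequency bins by average
expression (ties by gene id) and, per signature gene, samples 100 control
genes from its bin (with replacement if the bin is smaller); the score is
mean signature expression minus mean control expression per cell. With very
few genes per bin the controls can collapse onto the signature gene itself,
so `nbin` should be well below n_genes/10.

Malignancy is the conjunction of the applicable criteria: droplet
protocols skip the CNA criterion (sparse UMI data make the windowed-mean
statistic unreliable), as do datasets without reference normals; a dataset
with no annotated normal clusters at all is called entirely malignant.
Malignant cells with module score strictly above 0 over the NGS signature
are NGS+; a score of exactly 0 (possible with sparse data) falls to NGS-
so that NGS+ remains the strict positive class. The default 34-gene
signature ships with the 11 literature-named NGS genes (PTPRS, MAP2,
CADM1, NLGN3, GABBR1, NRCAM, GLRB, GRIA4, GRIK3, INA, GRIA2) padded with
synthetic ids; real analyses should supply their own list.

## Triplex alignment

Affinity is the Smith-Waterman local alignment score under the triplex
pairing code with match +1, mismatch -1, gap open -2, gap extend -1, so a
perfect contact scores its length in bp and the binding threshold of 100
corresponds to roughly 150 bp once mismatches and gaps discount the score.
Both duplex strands are scanned; the antiparallel motif aligns the
reversed RNA. Multiple sites are recovered by masking the DNA interval of
the best alignment and realigning (up to 25 iterations) — simpler than
full Waterman-Eggert suboptimal alignment and sufficient for building
peak-like DBSs. Exotic triplex contacts (e.g. G.(T:A)) are deliberately
omitted. DBSs are unions of overlapping TTS intervals kept when longer
than 50 bp (strict), with affinity the maximum member affinity. Promoter
windows run 3,500 bp upstream to 1,500 bp downstream of the strand-aware
TSS, reverse-complemented for minus-strand genes, clipped at contig ends.
This is a declared simplification of full triplex-prediction programs; it
is not intended to reproduce any genome-wide DBS catalogue.

## Network statistics

The Bayesian correlation of two genes models each cell's counts as
multinomial with a symmetric Dirichlet prior (pseudocount 1): posterior-mean
rates `(count + 1)/(total + n_genes)` are correlated with Pearson's r,
converging to the plain rate correlation at high depth; p-values come from
the t-statistic at n-2 df and are BH-adjusted across all tested pairs of
one dataset. An edge requires correlation > 0.4 (signed, as printed),
adjusted p < 0.05, and a promoter DBS with affinity > 100 — all strict. A
correlated pair with no DBS call is treated as non-binding and logged.

The permutation test draws the number of DBS-carrying genes in each
resample directly from the hypergeometric distribution — mathematically
identical to sampling the genes without replacement, and fast enough for
10^6 resamples in well under a second. The default estimate is
`(1 + hits)/(n_perm + 1)` so that zero hits reports < 1/n_perm rather than
0; `plus_one=False` gives the plain ratio of resamples.

Fisher enrichment of NGS+ cells in a survival-associated group uses the
one-sided exact test on the (group vs rest-of-background) x (NGS+ vs NGS-)
table; the background is a parameter because group-vs-background and
group-vs-complement constructions answer different questions and published
analyses are not always explicit about which was used.

## Synthetic data

The generator is the package's test bed and defines its study conditions:
1,600 genes over 8 chromosomes plus chrM, three normal types x 200 cells
with 20 near-exclusive markers each (off-state mean 0.05 counts, on-state
fold 60 — cell-type markers behave as on/off switches, so the fold is
large), 500 malignant cells carrying a +0.5 log2 gain over 200 chr7 genes,
a 34-gene NGS program at fold 2 in half the malignant cells, 10 lncRNAs,
negative-binomial counts with shared dispersion 10 and lognormal baseline
means around 5, and per-cell TPM scaling to 1e6 for the full-length
protocol.

lncRNA-target correlation is induced by a shared standard-normal latent
factor on the log-scale (log-sd 1.0). The loading is calibrated
analytically by inverting the attenuation that lognormal latent variance
and NB sampling noise impose on the count-level Pearson correlation, so
the realized correlation matches the configured strength (within 0.1 at
>= 500 cells) for the latent channel in isolation. When an orthogonal
group shift (the NGS fold) is overlaid on a target gene, the realized
correlation is further attenuated by a few hundredths; scenarios that test
the correlation channel therefore leave the NGS fold at 1.

Planted triplex tracts are homopyrimidine stretches (default 160 bp) in
the lncRNA paired with the matching homopurine tract in the target
promoter under the parallel motif; one tract per lncRNA is reused across
its targets, as a DNA-binding domain would be. Listing a pair only in the
correlation map or only in the tract map produces correlation-only or
binding-only decoys for end-to-end specificity tests.

What the simulations do **not** emulate: doublets, ambient RNA, batch
effects, dropout beyond NB sparsity, realistic gene-length or GC effects,
subclonal CNV structure, or sequence context around promoters. Passing
tests therefore demonstrate the correctness and calibration of the
algorithms under their stated assumptions, not performance on real tissue.

## Problem sizes and determinism

Default test and demonstration datasets use ~1,600 genes and ~1,100 cells,
enough for every planted effect to be estimated with comfortable margins
while keeping the full suite fast. Every stochastic step takes an explicit
seed (numpy `default_rng`; the Louvain RNG is seeded per call), and
generation is bit-identical under a fixed seed and config. The CLI covers
the file-in/file-out stages (simulate, preprocess, triplex, network,
permtest); the in-memory multi-step stages (clustering, CNA, scoring) are
driven through the library API, which is their intended interface.
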