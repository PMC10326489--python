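# Methods

This note documents the models, parameter choices and numerical
conventions behind `gbmdecon`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Scoring model

For cell type *t* with marker gene set *M_t* and bulk expression
*x_gs* (linear scale), the prevalence score of sample *s* is

    score(t, s) = mean over g in M_t of log2(x_gs + 1)

Linear-scale input is log2-transformed internally; input tagged as log
is used as given. Markers absent from the bulk matrix are dropped and
the remaining subset averaged — zeros are never imputed, because a
gene filtered out of a bulk matrix is missing, not unexpressed, and
zero-imputation would bias scores downward. The fraction of each type's
markers found is reported as coverage (warning below 0.5, error at 0).

Scores are relative: monotone in a cell type's abundance across
samples, but on an arbitrary per-type scale (marker sets differ in size
and baseline expression). Within-sample comparisons across cell types
are therefore meaningless by contract. The NNLS comparator
(`nnls_deconvolve`) solves min ||S p − x|| with p ≥ 0 per sample over a
genes × types signature matrix and renormalizes p to the simplex; it
yields proportions comparable within a sample, at the cost of needing
the full signature and being sensitive to its conditioning (a
rank-deficiency warning with the condition number is emitted).

## Reference building

**QC.** Per cell: total UMIs, detected genes, mitochondrial and
ribosomal count fractions, and complexity log10(nGene)/log10(nUMI)
(undefined at nUMI ≤ 1; such cells fail any complexity threshold).
Filtering is the conjunction of whichever thresholds are supplied;
thresholds are dataset-determined by the user, not defaulted.

**Normalization.** log-CPM: v = ln(1 + count·10⁴/cell_total), chosen as
a deterministic, dependency-light transform sufficient for marker
ranking. It satisfies Σ_g(e^v − 1) = 10⁴ per cell exactly, which the
tests use as a conservation oracle. Regularized-NB normalization and
confounder regression are deliberately not reimplemented; QC filtering
covers the main failure modes they address. Cross-dataset anchor
integration is out of scope — the pipeline assumes one batch-free
matrix (true for synthetic data); a pre-integrated matrix can be
supplied instead.

**CNV-based neoplastic exclusion.** Per gene, each cell's log
expression is centered on the all-cell mean (no reference population:
the baseline is the dataset average, so only subpopulation-restricted
events are visible), clipped to ±3 log units to limit outlier leverage,
and smoothed along genomic position with a centered moving average of
101 genes whose half-width shrinks symmetrically at chromosome edges.
A cell is flagged neoplastic when its mean smoothed score exceeds
+0.15 on the gain chromosome AND falls below −0.15 on the loss
chromosome (defaults chr7/chr10, the canonical IDHwt-GBM signature;
`mode="either"` trades specificity for sensitivity). The
window/clip/threshold defaults are this package's own: they are the
minimal moving-average core of expression-based CNV callers, with the
both-arms rule reflecting that the co-occurring +7/−10 pattern, not
either event alone, is the GBM hallmark.

**Clustering and annotation.** Top-2000 genes by log-expression
variance → 30 PCs → kNN graph (k = 20, Euclidean in PC space) → Leiden
community detection at resolution 0.7 with a fixed seed (deterministic;
permutation of cell order changes only labels). Clusters are annotated
by cross-tabulation against transferred per-cell labels: label L is
assigned iff count(L)/count(non-UNKNOWN) > 0.5 for exactly one L
(majority fraction and tie rule are this package's conventions; ties
and even splits are conservatively UNRESOLVED). UNRESOLVED clusters —
in real GBM data typically TAM/microglia and T/NK, whose transcriptomes
overlap — are isolated and re-clustered on their own variable genes
(fresh HVG and PCA on the subset), up to 2 rounds; clusters still
unresolved stay excluded from marker derivation. UMAP is available only
as a plotting aid, never on the computational path.

**Class balancing.** Classes above the cap (default 458) are sampled
without replacement down to exactly the cap; smaller classes are kept
whole. Deterministic per seed; different seeds differ only within
capped classes.

## Marker derivation

For every ordered cluster pair and gene: Welch t and Wilcoxon rank-sum
one-sided p-values for up-regulation in the first cluster (Wilcoxon via
the asymptotic normal approximation with tie and continuity correction;
exact enumeration is impractical at reference scale), and the mean
log-expression difference (lfc). Genes constant across both groups get
p = 1, lfc = 0; p-values are floored at 1e-300. Per focal cluster and
test, genes are ranked by p within each pairwise comparison (average
ranks on ties); `rank_any` is the best rank against any partner
(detects genes sharply up versus at least one cluster), `p_all` the
worst p against all partners (genes up versus every cluster). The two
tests are combined pessimistically (max of ranks, max of p): a marker
must look good under both. Selection keeps genes with min-lfc strictly
positive, orders by (rank, p, gene ID — a total, deterministic order)
and truncates to 25 per type; a gene claimed by several types goes to
the one where it ranks best (ties drop it everywhere). This
deterministic uniqueness rule replaces the visual specificity check a
human would perform on real data. A tumor-intrinsic filter removes
listed microenvironment-expressed genes from designated neoplastic
marker lists only.

## Cohort analysis

All-pairs Pearson correlation of cell-type score vectors across
samples, two-sided t-distributed p-values, BH adjustment over the
strict upper triangle. Stars (* < .05, ** < .01, *** < .001,
**** < .0001, else NS) are computed from raw p-values — matching the
usual figure-legend convention — with adjusted p reported alongside.
Survival stratification computes Q1/Q3 of overall survival by linear
interpolation between order statistics and assigns worse = OS strictly
below Q1, better = OS strictly above Q3, middle otherwise; middle
samples are retained in the output but excluded from the tail
comparisons. (The source literature for this design is internally
inconsistent about whether the better-prognosis boundary is the lower
or upper quartile; this package implements upper-quartile semantics,
the only reading under which the two tails are distinct.) Tail
comparison uses a two-sided Wilcoxon rank-sum per cell type with BH
adjustment across cell types, plus a within-tail rerun of the
correlation analysis. No survival modeling (Kaplan–Meier, Cox) is
attempted.

## Synthetic data generator

The generator is the package's test bed and defines the conditions the
test suite runs at. Defaults: 12 cell types (the 8 immune/myeloid
populations plus AC/MES/NPC/OPC), 3000 genes, 50 cells per type, 25
markers per type at log2 fold-change 2, negative-binomial counts with
shape θ = 2 around lognormal per-gene base means, lognormal per-cell
depth (mean 20 000 UMIs, log-sd 0.3), chr7 × 2 / chr10 × 0.5 dosage on
the four neoplastic types, genes placed round-robin on chromosomes
1–22, Dirichlet(1) mixing proportions over 50 bulk samples with 10%
multiplicative lognormal noise. The depth default reflects that the
3000-gene panel stands for the expressed transcriptome, so a droplet
cell's full UMI depth lands on it. Marker genes are drawn only from
chromosomes other than the CNV target arms, so marker identity is never
confounded with planted dosage events — the same reasoning behind
restricting neoplastic markers to tumor-intrinsic genes.

Pseudobulk is the exact convex combination of the TPM-normalized type
mean profiles (a matrix product, used as the noiseless NNLS oracle).
An optional latent per-sample factor multiplies the Dirichlet weights
of designated types by exp(±s·u), planting the mesenchymal-immune
covariance structure; tests use s = 2.0 because simplex normalization
cancels most of a factor shared by 9 of 12 types, and a weaker plant
would not stand above Dirichlet sampling noise (the planted-pattern
test is a sign-recovery check, not an effect-size estimate). Survival
times are exponential with a configurable median and an optional
log-scale link to a score vector.

**What the generator does not emulate:** batch effects between
datasets, ambient RNA and doublets, zero-inflation beyond NB sampling,
gene-gene correlation within cell types, subclonal CNV heterogeneity,
partial marker overlap between related cell types, or censoring in
survival data. Passing tests therefore demonstrate correctness of the
algorithms under a clean generative model, not field performance on
real tumors; accuracy on real data is bounded by reference quality and
the biological overlap of cell states.

## Numerical conventions

* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); CLI default seed 1.
* Scale inference for loaded matrices: all-integer → counts,
  max < 50 → log, else linear; a hint/flag overrides. Gene IDs match
  case-sensitively.
* Ties: average ranks inside rank statistics; lexicographic gene-ID
  tie-break in marker ordering (total order ⇒ bit-identical reruns);
  majority-label ties → UNRESOLVED; marker-uniqueness rank ties →
  gene dropped from all claimants.
* Degenerate inputs: all-zero cells are rejected by normalization
  (filter first); zero-variance vectors yield undefined correlations,
  excluded from means with a warning; an all-zero NNLS fit falls back
  to a uniform proportion vector with a warning.
* Scoring comparisons in tests use 1e-9 absolute tolerance; the
  log-CPM conservation oracle 1e-6 relative; round trips through TSV
  are lossless to 1e-9.

## Problem sizes used by tests and the acceptance script

Tests run the generator at its defaults (600 cells × 3000 genes);
seed-swept checks use 10 seeds for proportion recovery, marker
recovery and marker-set ordering, and 100 replicates for the
null-calibration checks. The acceptance script uses the same
conditions with 5 seeds for marker recovery; it completes in well
under a minute on a laptop-class core.
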