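# Methods

This note documents the statistical procedures implemented in `ecokit`,
their assumptions, the defaults that matter, and what the synthetic-data
validation does and does not demonstrate.

## Composition and Ro/e enrichment

A composition matrix holds, per sample, the fraction of its cells in each
cluster, over a declared denominator population: either all annotated
cells or only those flagged as microenvironmental (`tme_only`), which
removes e.g. malignant epithelium from both numerator and denominator.
Samples with no denominator cell are an error, not a zero row.

Ro/e compares observed cell counts per (cluster, group) with the
chi-square independence expectation E(c,g) = rowtotal(c)·coltotal(g)/N on
the full clusters × groups table built jointly across all clusters (one
table, not one per lineage — the convention behind a single enrichment
heatmap). Ro/e > 1 is enrichment. Zero-margin rows or columns yield
missing values rather than 0, distinguishing "absent" from "depleted".
Because the statistic pools cells, large samples dominate; an
`equal_sample` weighting option rescales every sample's counts to a
common total first. No significance test is attached: the ratio and the
\>1 threshold are the reported quantities.

## Bhattacharyya divergence between clinical groups

Transcriptional divergence of a cell population between two groups is
measured on a shared batch-corrected embedding (d ≈ 30) under a Gaussian
approximation. For Gaussians the Bhattacharyya distance
−ln ∫√(p·q) has the closed form

D_B = ⅛ Δμᵀ Σ̄⁻¹ Δμ + ½ ln( det Σ̄ / √(det Σ₁ det Σ₂) ), Σ̄ = (Σ₁+Σ₂)/2.

The Gaussian form was chosen because the distance is evaluated on smooth
low-dimensional embeddings and admits an exact numerical-quadrature
oracle (the tests verify agreement to better than three decimals on 1-D
and 2-D pairs with unequal covariances). With 50-cell subsamples in 30
dimensions raw covariances are near-singular, so each covariance is
shrunk toward the scaled identity tr(S)/d·I; the default intensity is the
Ledoit–Wolf data-driven estimate (`"auto"`), with any fixed λ ∈ [0,1]
available. At λ = 0 the distance is affinely invariant; singular pooled
covariances at λ = 0 raise an explicit error advising positive shrinkage.

The test statistic for a cluster: over `n_iterations = 100` iterations,
draw `subsample_size = 50` cells without replacement from each group and
record their distance (observed), and independently draw two disjoint
50-cell sets from the pooled cluster cells ignoring group labels (null).
The paired difference observed − null is reported with its mean as the
summary; under exchangeability the null pairing makes the difference
centre at zero, removing the positive bias that finite-sample covariance
estimation adds to every raw distance. Only clusters with more than
`min_cells_per_group = 200` cells in both groups are eligible; others are
flagged excluded. The pooled-split null is the default because the
construction of the randomized control is otherwise ambiguous; a
`within_group` variant (both null sets from the first group) is exposed.
Mean-of-differences equals difference-of-means for these paired
equal-length vectors.

## Ecotype discovery

**Input.** The samples × subclusters composition over microenvironmental
cells, transposed and min-max normalized per subtype ((x − min)/(max −
min) across samples, the conventional orientation for abundance NMF);
zero-variance subtypes are dropped and recorded.

**Factorization.** NMF minimizes the generalized KL divergence
D(V‖WH) = Σ V log(V/WH) − V + WH with Brunet multiplicative updates
(update factors normalized by the column sums of W and row sums of H),
which keep the objective non-increasing — asserted to 1e-10 per step in
the tests. Entries of W and H are initialized i.i.d. uniform(0, max V)
from the run's seed and floored at 1e-12. Iterations cap at 500;
runs stop early when the relative objective change stays below 1e-9 for
40 consecutive iterations.

**Rank selection.** For each rank 2–10, 100 seeded runs are reduced to
sample connectivity matrices (1 if two samples share the argmax factor);
their mean is the consensus matrix. The cophenetic correlation between
the (1 − consensus) dissimilarities and the cophenetic distances of an
average-linkage tree on them scores stability; a perfectly block-binary
consensus scores exactly 1, and a completely flat consensus is treated as
trivially stable. The recommended rank maximizes the coefficient, ties
to the smaller rank — interpretability, which the original workflow
weighed informally, is not computable, so a deterministic rule is used.
Survey runs use a 200-iteration cap (stability of the argmax partition
saturates well before the objective does); the final model uses the full
500.

**Final fit.** `EcotypeModel.fit` keeps the best of `n_init = 10` seeded
500-iteration runs by final KL objective (the nrun-style best-fit
convention of consensus-NMF software). Multiplicative updates are
init-sensitive; a single run can land in a local optimum that merges two
composition blocks even when the rank survey is unambiguous.

**Features and assignment.** Each subtype row of W is normalized to a
distribution p over factors and scored 1 + (1/log₂k) Σ p log₂ p — 1 for
a factor-specific row, 0 for a uniform one. Rows scoring above
median + 3·MAD (raw, unscaled MAD) are representative of their argmax
factor. When all scores tie exactly (MAD 0, e.g. a strictly
block-diagonal W) the threshold degenerates to the median with positive
specificity still required, so fully specific rows are all selected and
uniform rows never are. This is an outlier criterion: on data where most
subtypes are factor-specific it may select none, which is reported (with
a warning), not an error. Samples go to their argmax coefficient factor,
ties toward the lowest factor index; all-zero columns are unassigned.

**Companion analyses.** Samples are also clustered hierarchically with
the classic 'ward.D' Lance–Williams update applied directly to the
Euclidean distances of the composition rows — deliberately not scipy's
`ward` (= 'ward.D2', which squares within the recurrence); a frozen
R `hclust` oracle pins the semantics. Ties break toward the
lexicographically smallest cluster ids; the update coefficients sum to 1,
so merge heights are monotone. Because the two partitions answer the
question differently, the results object reports the NMF assignment, the
Ward cut at the same rank and their cross-tabulation without merging
them. The abundance co-occurrence network uses pairwise Spearman
correlations across samples with two-sided p-values (t approximation;
exact permutation enumeration for n ≤ 9 samples) and Benjamini–Hochberg
adjustment over all unordered pairs, keeping edges at adjusted p ≤ 0.05.

## Signatures, scoring and meta-analysis

**Markers.** One-vs-rest two-sided Wilcoxon rank-sum per gene and
cluster (mid-rank ties, normal approximation; exact enumeration when both
sides have ≤ 10 cells), with avg_log2FC = log₂((mean expm1 in + 1)/(mean
expm1 out + 1)) on the log-normalized scale. Bonferroni control is over
the widest family, genes × clusters. Exact parity with any particular
single-cell toolkit's fold-change convention is a non-goal; the
convention here is pinned and tested.

**Signatures.** Per cluster: keep p_adj ≤ p_filter, sort by fold change
descending (ties lexicographic by gene), truncate to k. Cluster
signatures use k = 50 at p ≤ 0.05; group signatures pool per-subcluster
top-20 lists at p_adj ≤ 1e-4 and assign each pooled gene to the single
group with maximal mean expression ("expression preference"; ties to the
first declared group, flagged).

**Module score.** Genes ranked by overall mean expression are cut into
`n_bins = 24` equal-frequency bins; each signature gene draws
`n_controls` control genes from its bin without replacement (100 for
per-cell scoring, 50 for bulk/spot scoring — the documented defaults of
the two scoring conventions this reproduces); the score is the mean
signature expression minus the mean over the pooled unique controls. On
a constant matrix the score is exactly 0, and expression-matched random
sets centre at 0.

**Meta-analysis.** DerSimonian–Laird: fixed weights wᵢ = 1/SEᵢ², Q =
Σwᵢ(θᵢ − θ_FE)², τ² = max(0, (Q − (n−1))/(Σw − Σw²/Σw)), random weights
1/(SEᵢ² + τ²), 95% CI = pooled ± 1.96/√Σw*. The implementation is
cross-checked against statsmodels' `combine_effects` to 1e-10. How
per-dataset effects are constructed is left to the caller; a helper
dichotomizes scores at the median and returns a Haldane-corrected log
odds ratio, flagged as one possible convention among several.

## Synthetic data

The generator emulates a grouped single-cell cohort at desk scale, not an
integrated atlas: samples (default 2 groups × 20) receive ecotype labels
cyclically; each sample's subcluster composition is a multinomial draw
from a Dirichlet sample of its ecotype's concentration row
(block-structured by default: concentration 6 on the ecotype's block, 0.3
elsewhere — well-separated profiles); cell totals are negative-binomial
(mean 600, dispersion 5) for realistic overdispersion, or fixed.
Embeddings are isotropic Gaussians (sd `noise_sd` = 1) at deterministic
axis-aligned centroids `cluster_spacing` = 8 apart; remodeled subclusters
displace their last-group cells by `shift_magnitude` along the diagonal
unit direction, so the population Bhattacharyya distance between the two
group distributions is exactly δ²/(8·noise_sd²). Expression is
exponential background (scale `noise_sd`, a non-negative heavy-tailed
stand-in for log-normalized values — `noise_sd` deliberately doubles as
the expression noise scale so marker effects are expressed in noise-sd
units) plus `marker_log_fold` added to each subcluster's disjoint marker
block. One global seed expands to per-stage child seeds as
(seed + crc32(stage)) mod 2³¹, so any stage reruns identically in
isolation.

What passing tests show: the estimators recover planted composition
structure, embedding shifts and markers under clean, well-separated,
isotropic conditions. What they do not show: robustness to batch
effects, doublets, ambient RNA, unbalanced or correlated noise,
continuous (non-blocky) ecotype gradients, or annotation error — none of
which the generator simulates.

## Problem sizes and numerical choices

The shipped demo pipeline and test suite run at reduced sizes chosen to
exercise every code path on one CPU in minutes: composition matrices of
9–12 subtypes × 20–40 samples, rank surveys of 2–10 × 100 runs (the full
grid) on those matrices, divergence tests at 100 iterations × 50-cell
subsamples over ~4,000-cell clusters, and expression of a few hundred
genes. Degenerate inputs are explicit errors (singular covariances at
λ = 0, all-constant abundance matrices, rank > min dimension, SE ≤ 0) or
flagged results (excluded clusters, unassigned samples, empty feature
lists); ties everywhere have documented deterministic rules (smaller
rank, lowest factor index, lexicographic genes/clusters, first group).

## Known limitations

- The Gaussian closed form underestimates divergence for strongly
  non-Gaussian embedding clouds; no density-estimation alternative is
  provided.
- Cophenetic rank selection degrades when consensus matrices are nearly
  flat across ranks; the survey is reported so users can inspect it
  rather than trust the argmax blindly.
- The Kim–Park-style feature criterion is an outlier rule and can return
  empty feature lists on small or uniformly specific basis matrices.
- Ro/e pools cells across samples by default, so large samples dominate
  unless `equal_sample` weighting is chosen.
- The meta-analysis helper's median dichotomization is one of several
  defensible effect constructions; results should be checked against the
  caller's own effect definition.
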