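# ecokit

Sample-level ecology of the tumor microenvironment (TME) from annotated
single-cell data. Given per-cell annotations (sample, clinical group,
lineage, subcluster), a shared low-dimensional embedding and a
log-normalized expression matrix, `ecokit` answers four questions that
recur in atlas-scale cancer studies — here motivated by prostate-cancer
progression from hormone-sensitive to castration-resistant disease, but
applicable to any grouped single-cell cohort:

1. **Which cell states expand or contract between clinical groups?**
   Ro/e enrichment — the ratio of observed to expected cell counts per
   (subcluster, group) cell of the contingency table, with expectations
   from the chi-square independence model; Ro/e > 1 marks enrichment.
2. **Which cell states change transcriptionally, not just numerically?**
   Subsampled Bhattacharyya divergence on embeddings: repeated 50-cell
   subsamples per group, a matched null from random splits of the pooled
   cells, and the paired difference (observed − null) as the statistic.
   For Gaussians, D_B = ⅛ Δμᵀ Σ̄⁻¹ Δμ + ½ ln(det Σ̄ / √(det Σ₁ det Σ₂)),
   with Ledoit–Wolf covariance shrinkage for small subsamples.
3. **Do samples organize into recurrent microenvironment "ecotypes"?**
   Consensus non-negative matrix factorization of the min-max-normalized
   subtypes × samples abundance matrix, minimizing the generalized
   Kullback–Leibler divergence D(V‖WH) with Brunet multiplicative
   updates; the factorization rank is selected by the cophenetic
   correlation of consensus matrices over 100 seeded runs per rank, and
   samples are assigned to their argmax factor. A companion 'ward.D'
   hierarchical clustering and a Spearman/Benjamini–Hochberg abundance
   co-occurrence network describe the same structure from other angles.
4. **Do ecotype signatures generalize to bulk cohorts?** One-vs-rest
   Wilcoxon markers with Bonferroni control, top-k signatures,
   binned-control module scores (mean expression of the gene set minus
   expression-matched controls), and DerSimonian–Laird random-effects
   pooling of per-dataset effect estimates.

A seeded synthetic-data generator plants ecotypes (Dirichlet–multinomial
composition), group-specific embedding shifts of known magnitude and
subcluster marker genes, so every stage can be validated against ground
truth.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from ecokit import SimulationConfig, simulate_composition, EcotypeModel

# 12 subclusters: one specific driver per planted ecotype + 9 shared
alpha = np.full((3, 12), 2.0)
for e in range(3):
    alpha[e, e] = 25.0
cfg = SimulationConfig(n_groups=2, n_samples_per_group=10, n_subclusters=12,
                       k_ecotypes=3, dirichlet_alpha=alpha,
                       cells_per_sample=400, seed=7,
                       n_genes=60, n_markers_per_subcluster=5)
counts, truth, _ = simulate_composition(cfg)
comp = counts.div(counts.sum(axis=1), axis=0)

res = EcotypeModel(comp, ranks=range(2, 7), runs_per_rank=50).fit(seed=7)
print(res.summary())
print("ARI vs planted ecotypes:", adjusted_rand_score(truth, res.assignment))
```

prints

```
Ecotype discovery (consensus NMF, KL/brunet)
====================================================
samples: 20   subtypes: 12   dropped (zero variance): 0
rank survey (cophenetic): k=2: 0.996, k=3: 1.000, k=4: 0.993, k=5: 0.986, k=6: 0.909
recommended rank: 3   fitted rank: 3
final KL objective: 18.144 (174 iterations)

factor sizes and representative subtypes:
  F1: 7 samples | SC01
  F2: 6 samples | SC03
  F3: 7 samples | SC02

NMF vs ward.D cross-tabulation:
cluster  1  2  3
factor          
1        7  0  0
2        0  6  0
3        0  0  7

ARI vs planted ecotypes: 1.0
```

The cophenetic survey peaks at the planted rank 3 (consensus perfectly
stable); the basis-specificity score recovers exactly the three planted
driver subclusters as representative features; sample assignment matches
the planted ecotypes (adjusted Rand index 1.0) and the independent
'ward.D' partition agrees factor-for-factor.

## Command line

Every stage is also a subcommand of the umbrella CLI:

```bash
ecokit simulate --seed 3 --out-dir data/
ecokit composition --cells data/cells.tsv --out comp.tsv
ecokit roe --cells data/cells.tsv --out roe.tsv
ecokit diverge --cells data/cells.tsv --embeddings data/embeddings.tsv \
       --cluster SC01 --groups G1,G2 --seed 7 --out div.tsv
ecokit ecotype --composition comp.tsv --ranks 2:6 --runs 50 --out-dir eco/
ecokit run --out-dir demo/     # full pipeline on a built-in demo config
```

All interchange formats are headed TSV (MatrixMarket triplets with name
sidecars for sparse expression); `ecokit run` writes a `manifest.json`
with parameters, per-stage seeds and output checksums — two runs with the
same config are byte-identical.

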