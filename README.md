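# lea — k-nearest-neighbor Local Enrichment Analysis

`lea` implements Local Enrichment Analysis (LEA): per-cell statistical
testing in the class-probability space of an image-based single-cell
classifier. When a convolutional network scores millions of cells against
C cell classes, its confidence vectors form a C-dimensional phenotype
landscape in which morphologically similar cells cluster together — even
within a single "hard" class. LEA asks, for every single cell, whether its
local neighborhood in that landscape is enriched for a condition
(a drug treatment, a donor, a sex) or associated with a continuous
donor-level variable (age, blood pressure, a gene's bulk expression), and
assigns the resulting significance back to the cell. It is aimed at
high-content-screening and immune-phenotyping groups who already have
per-cell classifier probabilities and per-cell metadata and want
statistically calibrated phenotype maps rather than cluster-level counts.

## The statistics

For each cell, the k nearest neighbors (default k = 400; k = 200 for
focused single-lineage analyses) are found in the **original**
C-dimensional probability space under the Euclidean metric
(Mahalanobis optional).

**Discrete conditions.** With N cells total, K of condition X, and n of
them among the k neighbors, the enrichment p-value is the hypergeometric
upper tail

    p = P(H ≥ n),   H ~ Hypergeometric(N, K, k)

**Continuous donor variables.** Per cell, the fraction of neighbors
contributed by each donor is computed; these fractions are rank-correlated
(Spearman's ρ) with the variable across donors and the two-sided
significance of ρ is the per-cell p-value. For ≤ 9 donors the permutation
p is computed exactly by full enumeration of the d! orderings; for ≥ 10
donors the t-approximation with d − 2 degrees of freedom is used.

Per-cell p-values are Bonferroni-corrected by the number of cells (=
tests), and maps are drawn from the signed score −log10(p) · sign, where
sign is +1 for enrichment and sign(ρ) for associations. Whole-map
significance is calibrated by a randomization null: labels are shuffled
(cell-level for discrete, donor-level for continuous), the summed
enrichment Σ −log10(p_adjust) is recomputed per shuffle, and the observed
sum is compared to the null sums by a one-sided t-test plus an empirical
permutation p.

On top of the core method the package provides phenotype-to-transcriptome
association (a gene's per-donor bulk abundance as the continuous
variable), two pathway summaries (per-cell in-pathway vs background
t-test; hypergeometric overlap of a pathway with the top 5% positively
associated genes), an AROC consistency benchmark, signed median-ratio and
percentile-bin group statistics, and radius-based cell-cell interaction
scores per well (score(A,B) = observed neighbor pairs / fracA·fracB·total,
≈1 under spatial randomness, log2-normalized against a control condition).
A synthetic-data generator (Dirichlet mixtures with planted enrichments,
gradients, signal genes and spatial attraction) makes every statistic
testable without images or trained networks.

## Worked example

```python
import lea

spec = lea.SyntheticSpec(n_donors=6, cells_per_donor=500)   # 3000 cells, 8 classes
data = lea.simulate(spec, seed=7)                           # plants a condition in cluster 0
idx = lea.build_knn(data["probabilities"], k=100)
res = lea.lea_discrete(idx, data["cells"].column("condition"), "stimulated")
print(res.table.head(4).to_string(index=False))
```

```
    cell_id  n_in_neighborhood            p     p_adjust  signed_score
cell_000000                 57 7.134889e-23 2.140467e-19     22.146613
cell_000001                 10 9.523925e-01 1.000000e+00      0.021184
cell_000002                  8 9.900936e-01 1.000000e+00      0.004324
cell_000003                  8 9.900936e-01 1.000000e+00      0.004324
```

Cell 0 sits in the planted cluster: 57 of its 100 neighbors are
"stimulated" cells against a landscape-wide ~15% background, so its
neighborhood enrichment survives Bonferroni correction over all 3000
cells (p_adjust ≈ 2e-19, signed score 22.1). Cells 1–3 sit in unplanted
clusters and are flat. Summarizing recovery and calibration:

```python
print((res.p_adjust < 0.05).sum())        # 378 significant cells ...
in_cluster = data["truth"].cells["cluster"] == 0
print((res.p_adjust[in_cluster.to_numpy()] < 0.05).sum())  # ... all 378 in the planted cluster

ns = lea.randomization_null(idx, labels=data["cells"].column("condition"),
                            n_perm=50, seed=7)
print(f"{ns.observed:.1f} vs max null {ns.null_sums.max():.1f}, "
      f"empirical p {ns.p_empirical:.4f}")
# 5557.9 vs max null 13.6, empirical p 0.0196
```

The observed sum-enrichment (5557.9) exceeds every one of 50
label-shuffled sums (max 13.6): the condition structure in the
probability landscape is far beyond chance.

The same analyses are available from the shell:

```bash
lea simulate --seed 7 --outdir sim/
lea discrete --probs sim/probabilities.tsv --cells sim/cells.tsv \
    --condition condition=stimulated --k 100 --out enrichment.tsv
lea interactions --cells sim/spatial_cells.tsv --radius 40 --out scores.tsv
```

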