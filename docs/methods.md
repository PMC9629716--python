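# Methods

## The model

LEA treats the per-cell output of a C-class single-cell classifier — a
probability vector on the C-simplex — as a phenotype coordinate. The
premise is that a well-trained classifier's *uncertainty* is informative:
cells of the same class but different morphology or marker profile land in
different parts of the class's probability "cloud", so local neighborhood
composition in this space carries biological signal that hard class
labels discard.

For every cell i, the k nearest other cells are found in the raw
probability space (the center cell is excluded from its own neighborhood:
including it would add one guaranteed success to every discrete test and
bias enrichment upward). Two tests are assigned back to cell i:

- **Discrete.** With N analysis cells, K of condition X, and n X-cells
  among the k neighbors, p = P(H ≥ n) with H ~ Hypergeometric(N, K, k).
  The population is all N cells of the analysis, including the center.
- **Continuous.** The neighbor count of each donor divided by k (the
  "neighborhood fraction") is Spearman-correlated with a per-donor
  variable; the two-sided significance of ρ is the p-value, and its sign
  is carried into the signed score.

Multiple testing is corrected by Bonferroni over the number of cells
(p_adjust = min(1, p·N)), deliberately conservative: a per-cell map is N
dependent tests. The signed map score is −log10(p)·sign computed from the
**raw** p with the sign attached (+1 for discrete enrichment, sign(ρ) for
associations); the adjusted p is reported in the same table and is the
recommended discovery threshold. Raw p is used for the score because with
few donors the smallest attainable permutation p (2/d!) cannot pass a
Bonferroni cap over thousands of cells, which would collapse every map to
zero; the raw-p score preserves the ordering and sign, while p_adjust
preserves calibrated discovery.

All p-values are floored at the smallest positive normal double
(≈ 2.23e-308) before logging, so signed scores are finite with a maximum
magnitude of ≈ 307.65.

## Neighborhoods

Exact KNN is computed by chunked exhaustive distance evaluation with a
stable sort, so distance ties break by ascending cell index and results
are independent of chunking. Euclidean distance on the raw probability
rows is the default. Mahalanobis is selectable; because simplex rows sum
to one the covariance is rank-deficient, so the inverse covariance is a
pseudo-inverse of (cov + 1e-8·I), and a warning reports the rank
deficiency. Approximate-NN backends are intentionally not used: the exact
index is the contract that the enumeration oracles test against.

Defaults: k = 400 for whole-landscape analyses, k = 200 for single-lineage
analyses (the CLI `genes` command). As a rule of thumb k near √N behaves
well; k far below that makes the discrete test very granular, k near N
washes out locality.

## Continuous p-values: exact vs approximate

For d donors the Spearman permutation distribution is enumerated exactly
for d ≤ 9 (d! ≤ 362,880; vectorized as a matrix product of z-scored
midranks, so ties in the neighborhood fractions — frequent, since counts
are small integers over k — are conditioned on exactly). For d ≥ 10 the
t-approximation t = ρ√((d−2)/(1−ρ²)) with d−2 df is used. Zero-variance
fraction vectors (every donor equally represented) are reported with
ρ = 0, p = 1 and a `degenerate` flag. Donors missing the tested variable
are excluded per-analysis: their cells keep their places in the geometry
but are not counted toward any donor fraction.

## Randomization null

The whole-map statistic is Σ_cells Σ_conditions −log10(p_adjust),
identical for observed and permuted runs. Discrete labels are permuted at
the cell level; continuous variables at the donor level. Significance is
reported two ways: a one-sample one-sided t-test of the null sums against
the observed value (alternative: null mean < observed), and the empirical
p (1 + #{null ≥ observed})/(n_perm + 1). If the null sums are constant the
t-test is undefined and only the empirical p is reported, with a warning.
The default n_perm is 2000; the validation script uses 50 permutations for
the planted-effect check and, for the no-effect specificity check, 18
permutations — the largest count for which the attainable empirical-p grid
{1/19, …, 1} places the 0.1 reference level a full grid step above the
minimum, so the check is not dominated by grid-boundary effects — across
100 independent runs.

## Associations and pathway summaries

Gene association is continuous LEA with the gene's per-donor bulk
abundance as the variable; a gene constant across donors returns ρ = 0,
p = 1 rather than an error. The per-cell pathway t-test compares
in-pathway gene scores against all other genes' scores with Welch's
unequal-variance t-test (the pooled-variance form is a flag; Welch is the
default everywhere a two-sample t-test appears, for robustness to the
very unequal group sizes of pathway vs background). Direction is the sign
of the mean difference. The hypergeometric pathway variant takes the top
set as genes above the 0.95 quantile computed over positively associated
genes only (an all-genes quantile is a flag), tests each pathway's overlap
against the measured-gene population, and Bonferroni-corrects over
pathways.

AROC uses the rank-based (Mann–Whitney) definition with ties counted
half. The signed group difference scores −log10(p)·sign(1 −
median(pos)/median(neg)); the percentile-bin statistic assigns cells to
within-well equal-frequency bins (ties to the lower bin), averages the
response per well and bin, and t-tests each bin's well means against the
last (reference) bin across replicate wells.

## Interaction scores

Cells interact when their centroids are within 40 px (inclusive) in the
same image site; sites are independent coordinate frames and are pooled
per well. Counting uses ordered pairs for both the pair-specific and the
total count: specific(A,B) is the number of ordered neighbor pairs
(a∈A, b∈B) and total is all ordered pairs (twice the unordered count).
This makes score(A,B) = specific/(fracA·fracB·total) exactly symmetric,
convention-stable (the shared factor 2 cancels), and ≈1 under random
labeling at large N. The alternative "interacting cells" total is
available as a flag for comparison. Undefined scores (no interactions, or
an absent class) propagate as NaN, never 0. Replicate aggregation takes
the mean score over wells per condition, log2-transforms, and subtracts
the control condition's value.

## Synthetic data

The generator emulates a multi-donor classifier-confidence landscape with
Dirichlet mixtures: each cell's row has concentration α_hi = 20 on its
own class and α_lo = 0.5 elsewhere, producing high-confidence class cores
plus uncertain boundary cells (argmax recovers the generating class for
>95% of cells). Desk-scale defaults: 8 classes, 10 donors, 1000
cells/donor, 200 genes (5 signal), 4 wells of 5000 cells over 4 sites of
1000×1000 px.

Planted effects and their parameterization:

- **Condition enrichment**: outside the cluster each cell is the
  condition with probability b = 0.1; inside, the odds are multiplied by
  10 (p_in = 10b/(1−b+10b) ≈ 0.53). These defaults give a strong but not
  degenerate effect — in-cluster neighborhoods roughly triple the global
  condition frequency.
- **Continuous gradient**: cluster cells' donors are resampled with
  probability ∝ exp(slope·z(variable)), slope 1.0; monotone by
  construction, so the planted contribution fraction is rank-perfect in
  the variable up to multinomial noise.
- **Expression**: signal genes are the z-scored per-donor cluster
  abundance plus N(0, 0.05) noise, shifted into a positive range and
  clipped at 0 (the table models normalized abundances, not counts);
  background genes are independent noise.
- **Spatial attraction**: 30% of class-a cells get a class-b partner
  placed within half the interaction radius.

Every generator is a pure function of (spec, seed), and every planted
effect is recorded in a JSON-serializable truth object.

What the generator does **not** model: classifier miscalibration beyond
the Dirichlet family, batch effects, well-position effects, cell-density
gradients within a site, donor-specific class composition differences,
and count-model noise in expression. Passing recovery tests therefore
demonstrates that the statistics detect the effects they are designed
for at realistic sizes — not that real imaging pipelines are free of the
confounders the generator omits.

## Validation conditions and numerical choices

The validation script (`scripts/acceptance.py`) runs at the following
problem sizes, chosen as the smallest scales at which the asymptotic
behavior of each statistic is visible: oracle checks at populations ≤ 12
(full enumeration), null calibration at N = 2000, k = 50 over 20
simulations, discrete recovery at N = 5000, k = 200, continuous recovery
at 10 donors × 1000 cells, k = 400, interaction calibration over 20 wells
of 5000 cells, and randomization-null behavior at N = 2000, k = 50.

Other numerical conventions: row sums of probability matrices are
validated to 1e-6 (an optional renormalization flag handles rounded
exports); the high-confidence filter is strict (> 0.7) with an inclusive
flag; balanced subsampling sorts cells canonically by id before drawing,
so it is invariant to input row order; KNN ties break by ascending index;
oracle comparisons are asserted to 1e-12.

## Known limitations

- The exact Spearman path enumerates d! orderings; beyond 9 donors it is
  deliberately unavailable (the t-approximation takes over).
- Bonferroni over cells is conservative under the strong dependence of
  overlapping neighborhoods; FDR-style corrections are out of scope.
- The discrete test conditions on K (the condition's total count), so it
  tests local arrangement, not abundance differences between wells.
- Interaction scores assume class fractions are well-estimated per well;
  very rare classes give noisy, occasionally undefined scores.
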