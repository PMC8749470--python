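# Methods

This note records the statistical model behind each pipeline stage, the
meaning of the parameters, the design and limitations of the synthetic
data generator, and the numerical choices that make runs reproducible.

## Normalization

Raw counts are normalized per cell to counts-per-`scale` (default 10,000)
and transformed with `log1p`:

x̃_cg = log(1 + scale · x_cg / Σ_g x_cg)

Cells with zero total count are left at zero and logged as a warning.
Normalizing an already-normalized matrix is an error rather than a silent
double transform.

## Cell typing

Each gene is z-scored across all cells (zero-variance genes are skipped).
A type's score for a cell is the mean z-score of that type's marker genes
that are present and variable; the cell gets the argmax type, with ties
going to the first type in input order. All-zero cells carry no evidence:
they receive the tie-break label and are flagged low-confidence. At least
two types with usable markers are required.

## Differential expression

Target type vs. all other cells, per gene, two-sided Wilcoxon rank-sum on
normalized expression.

- Both groups ≤ 8 cells: exact p by enumerating all C(n, n1) group
  assignments of the pooled midranks; two-sided p = min(1, 2 · min(tail)).
- Otherwise: normal approximation with the standard tie correction
  (σ² = n1·n2/12 · [(n+1) − Σ(t³−t)/(n(n−1))]) and a 0.5 continuity
  correction, vectorized across genes via one `rankdata` call.
- Constant genes get p = 1.

The reported effect size is
log2((mean expm1(target) + 1) / (mean expm1(rest) + 1)), i.e. a fold
change of per-cell normalized counts with a pseudocount of 1. A gene is
flagged DE when BH-adjusted p < `de_alpha` (default 0.05) and
|log2FC| ≥ `lfc_min` (default 0.25). BH adjustment is the classical
step-up procedure (`statsmodels` `fdr_bh`).

The exact and approximate branches agree to within ~0.01 absolute on
tie-free data at the branch boundary (n1 = n2 = 8). With heavy ties the
discrepancy can reach ~0.08 near p ≈ 1, an intrinsic property of the
doubled-tail convention vs. a continuity-corrected normal; it does not
affect small p-values.

## Neighborhood enrichment and selection

For candidate receptor R, the universe U is (expressed genes ∩ network
nodes) − {R}. With N = |U|, n = |neighbors(R) ∩ U|, K = |DE ∩ U| and
k = |neighbors(R) ∩ DE ∩ U|, the p-value is the hypergeometric upper tail
P(X ≥ k) = `hypergeom.sf(k−1, N, K, n)`. Candidates with empty
neighborhoods in U are reported with p = FDR = 1 but excluded from the BH
family (they carry no test). A candidate is *selected* when its BH FDR
across the scored candidates is below `selection_alpha` (default 0.05).

## Co-expression clustering and seed-cluster enrichment

Selected receptors are correlated (Spearman by default; Pearson available)
across target-type cells (`cell_scope="all"` uses every cell).
Zero-variance genes get correlation 0 and are reported. Agglomerative
clustering uses SciPy average linkage on the condensed distance
1 − correlation, cut into exactly `k` clusters (default 6); cluster ids
are relabeled 1..k by order of first appearance, so labels are
deterministic. The seed cluster is the one containing the seed genes
(default KDR, FLT1); if seeds split across clusters the majority cluster
wins (ties to the earliest-listed seed, with a warning).

The seed cluster is then tested against an annotation set (default
GO:0001525) with the same hypergeometric upper tail. The default universe
is the set of clustered genes (`universe_policy="clustered_genes"`);
`"scored_candidates"` uses all candidates instead. Note the granularity
floor: with a universe of N genes and a cluster of size n, the smallest
achievable p is 1/C(N, n), so small runs cannot produce very small
p-values regardless of how clean the signal is.

## Synthetic data generator

The generator plants known structure so that every stage has measurable
ground truth.

**Counts.** Gene g in cell c is negative binomial with mean μ_cg and
dispersion φ (`nb_dispersion`, var = μ + φμ²), sampled as a gamma–Poisson
mixture: λ ~ Gamma(shape 1/φ, scale φμ), count ~ Poisson(λ).

**Gene layout** (disjoint blocks): per-type marker genes (log2 boost
`marker_log2fc` in their own type), target-type DE genes (boost
`de_log2fc` in the target type only), true receptors, decoy receptors,
background. Baseline means are lognormal; receptors are drawn uniformly
in [1, 3] so their co-expression is observable at realistic depth.

**Modules.** True receptors are split round-robin into `n_modules`
blocks. In target-type cells each module adds a shared lognormal factor
to its receptors' log-means, drawn per cell with
z ~ N(−sd²/2, sd) so E[e^z] = 1: modules add co-variation without
systematic up-regulation. One module (`annotated_module_index`) is
covered exactly by the annotation gene set, and its first two receptors
are named KDR and FLT1 so downstream defaults work unmodified.

**Library size.** Each cell's expected profile is rescaled to a total
depth drawn lognormally around `mean_library_size`, independently of cell
type — sequencing depth is technical, so planted biology changes the
*composition* of a cell's counts, not its depth. A consequence worth
knowing: planting ≈5% of transcript mass into DE genes of the target type
depresses every other gene's relative abundance there by ≈4–5%, a real
compositional effect that global-normalization DE tests partially detect.
Evaluation therefore uses the standard benchmark FDR definition — a false
discovery is a flagged *truly null* background gene; markers and
module-bearing receptors are genuinely differential by construction and
count as true discoveries.

**Network.** Each receptor (true or decoy) gets exactly
`neighborhood_size` neighbors: a fraction `neighborhood_de_fraction_true`
(default 0.5) or `..._decoy` (default 0.05) drawn from the planted DE
genes, the rest from background genes. An Erdős–Rényi background with
`background_mean_degree` is laid over non-receptor genes. Neighborhood
composition is thus the *only* signal separating true receptors from
decoys; expression levels are matched.

**Limitations.** No doublets, ambient RNA, batch effects, or
gene–gene correlation outside the planted modules; dispersion is global
rather than mean-dependent; the network is unweighted and its background
is degree-homogeneous. The generator is a test harness for the pipeline's
statistics, not a full scRNA-seq emulator.

## Determinism and numerics

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  parameters (including seed) reproduce datasets and reports bit for bit.
- Report TSVs are written with `float_format="%.10g"`; repeated runs of
  the same config are byte-identical. The run manifest
  (`manifest.json`) records wall-clock stage timings and is therefore
  excluded from byte-identity comparisons.
- Hypergeometric tails use `scipy.stats.hypergeom.sf`, validated in the
  test suite against exact rational enumeration (≤ 1e-10 relative error
  for N ≤ 60).
- Cluster labels, candidate ordering, and gene ordering are all derived
  from input order, never from hash iteration order.
- Gene symbols are uppercased at every boundary; duplicate symbols keep
  the highest-total column.
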