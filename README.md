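# receptornet

Receptor prioritization from single-cell RNA-seq: find cell-surface
receptors whose network neighborhoods are enriched for genes upregulated in
a target cell type, then group the selected receptors into co-expression
modules and test the module containing chosen seed receptors for gene-set
enrichment.

## The problem

Single-cell expression alone rarely singles out which receptor drives a
cell type's behavior: many receptors are expressed, and expression level is
a weak proxy for functional relevance. A stronger signal is guilt by
association — if a receptor's direct neighbors in a gene–gene functional
interaction network are over-represented among the genes differentially
expressed (DE) in the target type, that receptor is likely wired into the
processes that make the type distinctive.

`receptornet` implements that idea as a reproducible pipeline:

1. **Normalize** raw counts per cell (counts-per-10k, log1p).
2. **Cell typing** from a marker table (or use provided labels).
3. **Differential expression**: Wilcoxon rank-sum, target type vs. all
   other cells, Benjamini–Hochberg FDR. Exact p-values for tiny groups,
   tie-corrected normal approximation otherwise.
4. **Neighborhood enrichment**: per candidate receptor, a hypergeometric
   upper-tail test of the overlap between its network neighbors and the DE
   gene set, BH-corrected across candidates; candidates with FDR below
   `selection_alpha` are *selected*.
5. **Co-expression clustering**: agglomerative clustering of selected
   receptors on 1 − Spearman correlation (average linkage) over
   target-type cells.
6. **Seed-cluster enrichment**: the cluster containing the seed receptors
   (default KDR/FLT1) is tested hypergeometrically against an annotation
   set (default GO:0001525, angiogenesis).
7. **Expression summaries**: per gene and cell type, the fraction of cells
   expressing and the mean normalized expression.

A planted-truth synthetic data generator (negative-binomial counts, marker
genes, target-type DE genes, true/decoy receptors with controlled
neighborhood composition, latent co-expression modules) makes every stage
testable end to end.

## Worked example

Simulate a small dataset with planted structure, then run the full
pipeline on it. `sim.yaml`:

```yaml
n_cells_per_type: {endothelial: 150, pericyte: 150, fibroblast: 150}
n_genes: 500
n_marker_genes_per_type: 5
n_de_genes: 40
n_true_receptors: 6
n_decoy_receptors: 12
neighborhood_size: 10
n_modules: 2
seed: 7
```

```sh
receptornet simulate --config sim.yaml --out data
```

`config.yaml` for the analysis (marker-based typing; `k: 2` because this
small dataset plants two receptor modules):

```yaml
expression_path: data/expression
network_path: data/network.tsv
gene_sets_path: data/gene_sets.gmt
candidates_path: data/candidates.tsv
markers_path: data/markers.tsv
out_dir: results
k: 2
```

```sh
receptornet run --config config.yaml
```

prints the written reports:

```
labels	results/labels.tsv
de_table	results/de_table.tsv
receptor_enrichment	results/receptor_enrichment.tsv
correlation_matrix	results/correlation_matrix.tsv
clusters	results/clusters.tsv
cluster_enrichment	results/cluster_enrichment.tsv
expression_summary	results/expression_summary.tsv
manifest	results/manifest.json
```

The receptor table recovers exactly the six planted true receptors
(`head -8 results/receptor_enrichment.tsv`):

```
candidate	neighborhood_size_in_universe	de_overlap	p_value	fdr	selected
KDR	10	5	0.005770665391	0.01731199617	True
FLT1	10	5	0.005770665391	0.01731199617	True
G0057	10	5	0.005359532721	0.01731199617	True
G0058	10	6	0.0006126853462	0.01102833623	True
G0059	10	5	0.005359532721	0.01731199617	True
G0060	10	5	0.005770665391	0.01731199617	True
G0061	10	0	1	1	False
```

Clustering splits the six selected receptors into the two planted modules,
and the seed (KDR/FLT1) cluster coincides with the annotated set
(`cat results/cluster_enrichment.tsv`):

```
cluster_id	gene_set_id	cluster_size	universe_size	set_size_in_universe	overlap	p_value
1	GO:0001525	3	6	3	3	0.05
```

(p = 1/C(6,3) = 0.05 is the floor for a universe this small; at realistic
scale — 15 selected receptors, 5-gene cluster — the same configuration
gives p ≈ 3.3e-4.)

Per-type summaries (`head results/expression_summary.tsv`):

```
gene	cell_type	n_cells	fraction_expressing	mean_normalized_expression
KDR	endothelial	150	0.9133333333	3.056978436
KDR	fibroblast	150	0.98	3.539930358
KDR	pericyte	150	0.9866666667	3.584543883
```

Every stage is also exposed as a subcommand (`receptornet de`,
`score-receptors`, `cluster`, `enrich`, `celltype`, `summarize`) and as a
plain Python API:

```python
from receptornet import (SimulationParams, simulate_dataset, normalize_log,
                         wilcoxon_de, score_candidates)

expr, labels, network, gene_sets, candidates, truth = simulate_dataset(
    SimulationParams(seed=0))
norm = normalize_log(expr)
de = wilcoxon_de(norm, labels, "endothelial")
table = score_candidates(network, de, set(norm.gene_ids), candidates)
print(table.loc[table.selected, "candidate"].tolist())
```

## Input formats

- Expression: 10x-style MatrixMarket triplet directory
  (`matrix.mtx` + `barcodes.tsv` + `features.tsv`) or dense TSV (either
  orientation, auto-detected).
- Network: two-column TSV edge list, undirected, self-loops dropped.
- Gene sets: GMT.
- Candidates: one symbol per line (optional second column: role).
- Labels / markers: two-column TSV.

Gene symbols are uppercased everywhere; duplicate symbols keep the column
with the largest total count.

## Reproduction

Run the test suite (includes one test per acceptance criterion: oracle
equivalence of the statistical primitives, parameter recovery over 10
seeds, null-control selection rate over 20 seeds, byte-identical reports):

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Run the acceptance script (≈35 s, one CPU):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With `--seed 1` this reports, over 10 default-scale recovery seeds
(5 types × 400 cells, 2000 genes, 15 true / 45 decoy receptors):
planted-DE recall 0.999, observed FDR 0.063, all 15 true receptors and 0
decoys selected on 10/10 seeds, module ARI 1.0, median seed-cluster
enrichment p = 3.33e-4; over 20 null seeds (`de_log2fc = 0`) a candidate
selection fraction of 0.0; and byte-identical reports across repeated
runs. All randomness derives from `--seed`.

See `docs/methods.md` for the statistical model, parameter meanings, and
numerical choices.
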