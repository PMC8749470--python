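"""Co-expression clustering of selected receptors/TFs and seed-cluster tests.

The selected candidates are clustered by the similarity of their expression
across single cells: pairwise correlation (Spearman by default) over a cell
scope (target cell type by default), agglomerative clustering on the
distance 1 - correlation with average linkage, cut to k clusters. The
cluster containing the seed receptors (KDR/FLT1 by default) is then tested
for gene-set over-representation with the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .enrichment import hypergeom_upper_tail
from .types import CellTypeLabels, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    genes: list[str]
    matrix: np.ndarray
    method: str  # spearman | pearson
    cell_scope: str
    zero_variance_genes: list[str] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    """gene -> cluster id in 1..k; ids ordered by first appearance."""

    assignment: dict[str, int]
    k: int
    linkage: str

    def members(self, cluster_id: int) -> set[str]:
        return {g for g, c in self.assignment.items() if c == cluster_id}


@dataclass
class EnrichmentResult:
    cluster_id: int
    gene_set_id: str
    cluster_size: int
    universe_size: int
    set_size_in_universe: int
    overlap: int
    p_value: float


def correlation_matrix(
    expr: ExpressionMatrix,
    genes: list[str],
    labels: CellTypeLabels | None = None,
    cell_scope: str = "all",
    target_type: str | None = None,
    method: str = "spearman",
) -> CorrelationMatrix:
    """Pairwise gene-gene correlation over the chosen cell subset.

    cell_scope 'target_type' restricts to cells labeled ``target_type``
    (the cell population the candidates were selected for); 'all' uses every
    cell. Zero-variance genes get correlation 0 with all others and are
    flagged.
    """
    genes = [g.upper() for g in genes]
    present = [g for g in genes if g in expr.gene_ids]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.warning("%d gene(s) absent from matrix: %s", len(missing), missing[:10])
    if len(present) < 2:
        raise ValidationError("need at least 2 genes present to correlate")

    if cell_scope == "target_type":
        if labels is None or target_type is None:
            raise ValidationError("cell_scope='target_type' needs labels and a type")
        keep = [i for i, c in enumerate(expr.cell_ids)
                if labels.labels.get(c) == target_type]
        scope_tag = f"target_type:{target_type}"
    elif cell_scope == "all":
        keep = list(range(expr.n_cells))
        scope_tag = "all"
    else:
        raise ValueError(f"unknown cell_scope {cell_scope!r}")
    if len(keep) < 3:
        raise ValidationError("need at least 3 cells in scope")

    cols = [expr.gene_ids.index(g) for g in present]
    X = expr.values[np.ix_(keep, cols)]

    var = X.var(axis=0)
    zero_var = var == 0
    # constant genes divide by a zero stddev inside corrcoef; their NaNs
    # are overwritten below, so silence only that expected warning
    with np.errstate(invalid="ignore"):
        if method == "spearman":
            R = X if X.shape[1] == 1 else stats.rankdata(X, axis=0)
            C = np.corrcoef(R, rowvar=False)
        elif method == "pearson":
            C = np.corrcoef(X, rowvar=False)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
    C = np.atleast_2d(C)
    # constant genes produce NaN rows; define their correlation as 0
    if zero_var.any():
        C[zero_var, :] = 0.0
        C[:, zero_var] = 0.0
        logger.warning(
            "%d zero-variance gene(s) set to correlation 0: %s",
            int(zero_var.sum()),
            [g for g, z in zip(present, zero_var) if z],
        )
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(
        genes=present,
        matrix=C,
        method=method,
        cell_scope=scope_tag,
        zero_variance_genes=[g for g, z in zip(present, zero_var) if z],
    )


def agglomerative_cluster(
    corr: CorrelationMatrix, k: int = 6, linkage_method: str = "average"
) -> ClusterAssignment:
    """Hierarchical clustering on distance 1 - correlation, cut to k clusters.

    Linkage is average by default (complete/single available for
    sensitivity analysis). Cluster ids are relabeled 1..k in order of first
    appearance along the input gene order, making the output deterministic
    for a fixed input order.
    """
    n = len(corr.genes)
    if k < 1 or k > n:
        raise ValidationError(f"k={k} out of range for {n} genes")
    D = 1.0 - corr.matrix
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    if n == 1:
        return ClusterAssignment({corr.genes[0]: 1}, 1, linkage_method)
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    raw = cut_tree(Z, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    assignment = {}
    for g, r in zip(corr.genes, raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        assignment[g] = relabel[r]
    return ClusterAssignment(assignment=assignment, k=k, linkage=linkage_method)


def find_seed_cluster(assignment: ClusterAssignment, seeds: list[str]) -> int:
    """Cluster holding the seed genes (e.g. the VEGF receptors KDR, FLT1).

    Returns the cluster of the first present seed; when seeds split across
    clusters the majority cluster wins (ties go to the earliest seed) and a
    warning is emitted.
    """
    seeds = [s.upper() for s in seeds]
    present = [s for s in seeds if s in assignment.assignment]
    if not present:
        raise ValidationError(f"no seed gene present in clustering: {seeds}")
    clusters = [assignment.assignment[s] for s in present]
    if len(set(clusters)) == 1:
        return clusters[0]
    logger.warning("seed genes split across clusters: %s",
                   dict(zip(present, clusters)))
    counts: dict[int, int] = {}
    for c in clusters:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    for c in clusters:  # earliest seed breaks ties
        if counts[c] == best:
            return c
    raise AssertionError("unreachable")


def cluster_geneset_enrichment(
    assignment: ClusterAssignment,
    cluster_id: int,
    gene_set: set[str],
    gene_set_id: str = "",
    universe: list[str] | None = None,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``gene_set`` in one cluster.

    Universe defaults to the clustered genes; pass an explicit list (e.g.
    all scored candidates) for the alternative policy.
    """
    cluster = assignment.members(cluster_id)
    if not cluster:
        raise ValidationError(f"cluster {cluster_id} is empty")
    if universe is None:
        universe_set = set(assignment.assignment)
    else:
        universe_set = {g.upper() for g in universe}
        if not cluster <= universe_set:
            raise ValidationError("cluster members missing from universe")
    gene_set = {g.upper() for g in gene_set}
    set_in_universe = gene_set & universe_set
    if not set_in_universe:
        raise ValidationError("gene set does not intersect the universe")
    k = len(cluster & set_in_universe)
    p = hypergeom_upper_tail(
        k, len(set_in_universe), len(cluster), len(universe_set)
    )
    return EnrichmentResult(
        cluster_id=cluster_id,
        gene_set_id=gene_set_id,
        cluster_size=len(cluster),
        universe_size=len(universe_set),
        set_size_in_universe=len(set_in_universe),
        overlap=k,
        p_value=p,
    )
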