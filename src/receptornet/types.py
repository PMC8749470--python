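"""Shared domain types for the receptor-prioritization pipeline.

The pipeline moves a single-cell expression matrix through cell typing,
target-vs-rest differential expression, network-neighborhood enrichment of
candidate receptors/TFs, and co-expression clustering.  Every stage consumes
and produces the containers defined here, so their invariants (uppercased
gene symbols, cells-as-rows orientation, undirected deduplicated network)
are enforced once, at construction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input violates a domain invariant (values, dimensions, emptiness)."""


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values.

    Parameters
    ----------
    cell_ids : list of str
        Barcodes, one per row. Must be unique.
    gene_ids : list of str
        Gene symbols, one per column. Uppercased and unique.
    values : ndarray, shape (n_cells, n_genes)
        Non-negative, finite. Raw counts or log-scale normalized values
        depending on ``normalized``.
    normalized : bool
        True if values are log-scale normalized, False for raw counts.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [g.upper() for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids after case-folding")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbol: str) -> int:
        return self.gene_ids.index(symbol.upper())

    def gene_vector(self, symbol: str) -> np.ndarray:
        """Expression of one gene across all cells."""
        return self.values[:, self.gene_index(symbol)]


def normalize_log(expr: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Per-cell library-size normalization followed by natural log1p.

    Each cell's counts are divided by the cell total, multiplied by
    ``scale`` (default 10,000) and transformed with ``log1p``.  This is the
    standard 10x/Seurat recipe for "log-scale normalized" values. Cells with
    zero total count are left all-zero and reported in the log.
    """
    if expr.normalized:
        raise ValidationError("input is already log-normalized")
    if scale <= 0:
        raise ValidationError("scale must be positive")
    totals = expr.values.sum(axis=1)
    zero_cells = totals == 0
    if zero_cells.any():
        logger.warning(
            "%d cell(s) have zero total count and stay all-zero: %s",
            int(zero_cells.sum()),
            [c for c, z in zip(expr.cell_ids, zero_cells) if z][:10],
        )
    safe_totals = np.where(zero_cells, 1.0, totals)
    out = np.log1p(expr.values / safe_totals[:, None] * scale)
    out[zero_cells] = 0.0
    return ExpressionMatrix(
        cell_ids=list(expr.cell_ids),
        gene_ids=list(expr.gene_ids),
        values=out,
        normalized=True,
    )


@dataclass
class CellTypeLabels:
    """Per-cell type assignment (cell_id -> cell-type name)."""

    labels: dict[str, str]
    low_confidence: set[str] = field(default_factory=set)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Every labeled barcode must exist in the companion matrix."""
        cells = set(expr.cell_ids)
        missing = [c for c in self.labels if c not in cells]
        if missing:
            raise ValidationError(
                f"{len(missing)} labeled cell id(s) absent from matrix, "
                f"e.g. {missing[:5]}"
            )
        if len(set(self.labels.values())) < 2:
            raise ValidationError(
                "at least two distinct cell types are required"
            )

    def types(self) -> list[str]:
        return sorted(set(self.labels.values()))


@dataclass
class GeneNetwork:
    """Undirected gene-gene interaction graph with set-valued neighbor queries.

    Holds the composite functional-interaction network used to define each
    candidate receptor's direct neighborhood. Self-loops are dropped and
    edges deduplicated irrespective of orientation at construction.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges) -> "GeneNetwork":
        g = nx.Graph()
        for a, b in edges:
            a, b = a.upper(), b.upper()
            if a == b:
                continue  # self-loop
            g.add_edge(a, b)
        if g.number_of_edges() == 0:
            raise ValidationError("network has no edges after cleanup")
        return cls(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, gene: str) -> set[str]:
        gene = gene.upper()
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.graph


@dataclass
class GeneSetCollection:
    """Mapping set_id -> member gene symbols, e.g. GO:0001525 (angiogenesis)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for sid, members in self.sets.items():
            members = {m.upper() for m in members}
            if not members:
                raise ValidationError(f"gene set {sid!r} is empty")
            cleaned[sid] = members
        self.sets = cleaned

    def __getitem__(self, sid: str) -> set[str]:
        return self.sets[sid]

    def __iter__(self):
        return iter(self.sets)


@dataclass
class CandidateList:
    """Ordered candidate receptor/TF symbols with a role tag per symbol."""

    symbols: list[str]
    roles: dict[str, str] = field(default_factory=dict)  # receptor | TF | unknown

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for s in self.symbols:
            seen.setdefault(s.upper(), None)
        self.symbols = list(seen)
        self.roles = {k.upper(): v for k, v in self.roles.items()}
        for s in self.symbols:
            self.roles.setdefault(s, "unknown")

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)
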