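"""Marker-based cell typing and per-cell-type expression summaries.

Cell types are assigned per cell by the argmax of marker scores: each
type's score is the mean of z-scored (across all cells) expression of its
marker genes. Summaries report, per gene and type, the fraction of cells
expressing (normalized value strictly above the detection threshold) and
the mean normalized expression — the quantities behind violin-plot style
per-type panels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CellTypeLabels, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def assign_cell_types(
    expr: ExpressionMatrix, markers: dict[str, set[str]]
) -> CellTypeLabels:
    """Label each cell with the type whose marker score is maximal.

    Marker genes absent from the matrix are dropped; types left with no
    usable marker are dropped with a warning. Genes with zero variance are
    skipped for scoring. Score ties go to the first type in input order
    (logged). Cells with no detected expression at all carry no evidence:
    they get the tie-break label and are flagged low-confidence.
    """
    if not expr.normalized:
        raise ValidationError("cell typing expects normalized expression")
    gene_pos = {g: j for j, g in enumerate(expr.gene_ids)}

    sd = expr.values.std(axis=0)
    usable_gene = sd > 0
    mean = expr.values.mean(axis=0)
    Z = np.zeros_like(expr.values)
    Z[:, usable_gene] = (expr.values[:, usable_gene] - mean[usable_gene]) / sd[usable_gene]

    type_names: list[str] = []
    type_cols: list[list[int]] = []
    for ctype, genes in markers.items():
        cols = [gene_pos[g.upper()] for g in genes
                if g.upper() in gene_pos and usable_gene[gene_pos[g.upper()]]]
        if not cols:
            logger.warning("cell type %r has no usable marker; dropped", ctype)
            continue
        type_names.append(ctype)
        type_cols.append(cols)
    if len(type_names) < 2:
        raise ValidationError("need at least 2 cell types with usable markers")

    scores = np.column_stack([Z[:, cols].mean(axis=1) for cols in type_cols])
    best = np.argmax(scores, axis=1)  # argmax takes the first maximum: input order
    ties = (scores == scores[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("%d cell(s) had tied marker scores; first type wins",
                    int(ties.sum()))

    all_zero = expr.values.sum(axis=1) == 0
    labels = {}
    low_confidence = set()
    for i, cell in enumerate(expr.cell_ids):
        if all_zero[i]:
            labels[cell] = type_names[0]
            low_confidence.add(cell)
        else:
            labels[cell] = type_names[best[i]]
    if all_zero.any():
        logger.warning("%d all-zero cell(s) labeled by tie-break and flagged "
                       "low-confidence", int(all_zero.sum()))
    return CellTypeLabels(labels=labels, low_confidence=low_confidence)


def summarize_expression(
    expr: ExpressionMatrix,
    labels: CellTypeLabels,
    genes: list[str],
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per (gene, cell type): n_cells, fraction expressing, mean expression.

    A cell "expresses" a gene when its normalized value is strictly above
    ``detection_threshold`` (default 0, the dropout-aware convention behind
    "% of cells expressing" statements). Genes absent from the matrix are
    reported and skipped.
    """
    if not labels.labels:
        raise ValidationError("empty label set")
    labels.validate_against(expr)
    genes = [g.upper() for g in genes]
    present = [g for g in genes if g in expr.gene_ids]
    absent = [g for g in genes if g not in expr.gene_ids]
    if absent:
        logger.warning("gene(s) absent from matrix, skipped: %s", absent)

    cell_types = sorted(set(labels.labels.values()))
    rows = []
    for gene in present:
        vec = expr.gene_vector(gene)
        for ctype in cell_types:
            idx = [i for i, c in enumerate(expr.cell_ids)
                   if labels.labels.get(c) == ctype]
            vals = vec[idx]
            n = len(vals)
            frac = float(np.mean(vals > detection_threshold)) if n else 0.0
            mean = float(vals.mean()) if n else 0.0
            rows.append((gene, ctype, n, frac, mean))
    return pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "n_cells", "fraction_expressing",
                 "mean_normalized_expression"],
    )
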