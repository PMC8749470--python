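"""Readers and writers for the pipeline's external formats.

Supported formats: MatrixMarket triplets with barcode/feature sidecars
(10x convention: genes as matrix rows, gene symbol in column 2 of
features.tsv), dense TSV expression tables, two-column TSV edge lists,
GMT gene-set collections, one-symbol-per-line candidate lists and
two-column cell label tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    CandidateList,
    CellTypeLabels,
    ExpressionMatrix,
    FormatError,
    GeneNetwork,
    GeneSetCollection,
    ValidationError,
)

logger = logging.getLogger(__name__)

_GENE_ROW_HINTS = {"gene", "genes", "symbol", "gene_symbol", "feature", "features"}
_CELL_ROW_HINTS = {"cell", "cells", "barcode", "barcodes", "cell_id"}


def _dedupe_genes(gene_ids: list[str], values: np.ndarray):
    """Resolve duplicate symbols by keeping the row with the largest total."""
    totals = values.sum(axis=0)
    best: dict[str, int] = {}
    for j, g in enumerate(gene_ids):
        if g not in best or totals[j] > totals[best[g]]:
            best[g] = j
    if len(best) < len(gene_ids):
        logger.warning(
            "dropped %d duplicate gene symbol(s); kept highest-total copy",
            len(gene_ids) - len(best),
        )
    keep = sorted(best.values())
    return [gene_ids[j] for j in keep], values[:, keep]


def read_expression(
    path: str | Path,
    fmt: str = "mtx10x",
    normalized_flag: bool = False,
    orientation: str = "auto",
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path : str or Path
        For ``mtx10x``: the directory holding ``matrix.mtx``,
        ``barcodes.tsv`` and ``features.tsv``, or the ``.mtx`` file itself.
        For ``dense_tsv``: the TSV file (row labels in the first column).
    fmt : {'mtx10x', 'dense_tsv'}
    normalized_flag : bool
        Whether on-disk values are already log-scale normalized. Explicit
        because deposited data may be either and the file cannot say.
    orientation : {'auto', 'cells_rows', 'genes_rows'}
        Dense-TSV only. 'auto' inspects the header of the first column for
        gene/cell hints and defaults to cells-as-rows.
    """
    path = Path(path)
    if fmt == "mtx10x":
        return _read_mtx10x(path, normalized_flag)
    if fmt == "dense_tsv":
        return _read_dense_tsv(path, normalized_flag, orientation)
    raise ValueError(f"unknown expression format {fmt!r}")


def _read_mtx10x(path: Path, normalized_flag: bool) -> ExpressionMatrix:
    if path.is_dir():
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
    else:
        mtx = path
        barcodes = path.parent / "barcodes.tsv"
        features = path.parent / "features.tsv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise FormatError(f"missing file for mtx10x triplet: {f}")
    mat = scipy.io.mmread(mtx)  # genes x cells on disk (10x convention)
    mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    cell_ids = [line.split("\t")[0] for line in _read_lines(barcodes)]
    feats = [line.split("\t") for line in _read_lines(features)]
    # gene symbol in column 2 when present (10x features.tsv), else column 1
    gene_ids = [f[1] if len(f) > 1 else f[0] for f in feats]
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix declares {mat.shape[0]} genes x {mat.shape[1]} cells but "
            f"sidecars list {len(gene_ids)} features and {len(cell_ids)} barcodes"
        )
    values = mat.T  # cells as rows
    gene_ids = [g.upper() for g in gene_ids]
    gene_ids, values = _dedupe_genes(gene_ids, values)
    return ExpressionMatrix(cell_ids, gene_ids, values, normalized_flag)


def _read_dense_tsv(
    path: Path, normalized_flag: bool, orientation: str
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "auto":
        hint = (df.index.name or "").strip().lower()
        if hint in _GENE_ROW_HINTS:
            orientation = "genes_rows"
        elif hint in _CELL_ROW_HINTS:
            orientation = "cells_rows"
        else:
            orientation = "cells_rows"
    if orientation == "genes_rows":
        df = df.T
    elif orientation != "cells_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy(dtype=float)
    gene_ids = [str(g).upper() for g in df.columns]
    gene_ids, values = _dedupe_genes(gene_ids, values)
    return ExpressionMatrix([str(c) for c in df.index], gene_ids, values, normalized_flag)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, fmt: str = "mtx10x"
) -> None:
    path = Path(path)
    if fmt == "mtx10x":
        path.mkdir(parents=True, exist_ok=True)
        mat = scipy.sparse.coo_matrix(expr.values.T)  # genes x cells on disk
        field = "integer" if not expr.normalized and np.allclose(
            expr.values, np.round(expr.values)
        ) else "real"
        if field == "integer":
            mat = mat.astype(np.int64)
        scipy.io.mmwrite(path / "matrix.mtx", mat, field=field, precision=17)
        (path / "barcodes.tsv").write_text("".join(c + "\n" for c in expr.cell_ids))
        (path / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in expr.gene_ids)
        )
    elif fmt == "dense_tsv":
        df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids)
        df.index.name = "cell"
        df.to_csv(path, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def _read_lines(path: Path) -> list[str]:
    return [ln for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_network(path: str | Path) -> GeneNetwork:
    """Read an undirected gene network from a two-column TSV edge list.

    Extra columns (weights, provenance) are ignored; edges are deduplicated
    irrespective of orientation and self-loops dropped.
    """
    lines = _read_lines(Path(path))
    if not lines:
        raise ValidationError(f"network file {path} is empty")
    edges = []
    for i, ln in enumerate(lines):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i + 1}: expected >=2 tab-separated columns")
        edges.append((parts[0], parts[1]))
    return GeneNetwork.from_edges(edges)


def write_network(network: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection (set id, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i, ln in enumerate(_read_lines(Path(path))):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i + 1}: GMT line needs >=3 fields")
        sid, desc, *members = parts
        sets[sid] = {m for m in members if m}
        descriptions[sid] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in collection:
            desc = collection.descriptions.get(sid, "")
            members = "\t".join(sorted(collection[sid]))
            fh.write(f"{sid}\t{desc}\t{members}\n")


def read_candidates(path: str | Path) -> CandidateList:
    """Read candidates: one symbol per line, optional tab-separated role."""
    symbols, roles = [], {}
    for ln in _read_lines(Path(path)):
        parts = ln.split("\t")
        sym = parts[0].strip()
        if not sym:
            continue
        symbols.append(sym)
        if len(parts) > 1 and parts[1].strip():
            roles[sym] = parts[1].strip()
    if not symbols:
        raise ValidationError(f"candidate file {path} lists no symbols")
    return CandidateList(symbols=symbols, roles=roles)


def write_candidates(candidates: CandidateList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in candidates:
            fh.write(f"{s}\t{candidates.roles.get(s, 'unknown')}\n")


def read_labels(path: str | Path) -> CellTypeLabels:
    """Read cell-type labels from a two-column TSV (barcode, type).

    A header line whose first field is a cell/barcode hint is skipped.
    """
    lines = _read_lines(Path(path))
    if not lines:
        raise ValidationError(f"label file {path} is empty")
    labels = {}
    for i, ln in enumerate(lines):
        parts = ln.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i + 1}: expected two tab-separated columns")
        if i == 0 and parts[0].strip().lower() in _CELL_ROW_HINTS:
            continue
        labels[parts[0]] = parts[1]
    return CellTypeLabels(labels=labels)


def write_labels(labels: CellTypeLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell\tcell_type\n")
        for cell, ctype in labels.labels.items():
            fh.write(f"{cell}\t{ctype}\n")


def read_markers(path: str | Path) -> dict[str, set[str]]:
    """Read a marker table: either two-column TSV (type, gene) or GMT."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        coll = read_gmt(path)
        return {sid: set(coll[sid]) for sid in coll}
    markers: dict[str, set[str]] = {}
    for i, ln in enumerate(_read_lines(path)):
        parts = ln.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i + 1}: expected two tab-separated columns")
        if i == 0 and parts[0].strip().lower() in {"type", "cell_type", "celltype"}:
            continue
        markers.setdefault(parts[0], set()).add(parts[1].upper())
    if not markers:
        raise ValidationError(f"marker file {path} is empty")
    return markers


def write_markers(markers: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_type\tgene\n")
        for ctype in markers:
            for g in sorted(markers[ctype]):
                fh.write(f"{ctype}\t{g}\n")
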