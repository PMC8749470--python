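"""End-to-end orchestration: normalize -> cell type -> DE -> neighborhood
enrichment -> co-expression clustering -> seed-cluster gene-set test ->
expression summaries, with a run manifest and TSV reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .celltyping import assign_cell_types, summarize_expression
from .clustering import (
    agglomerative_cluster,
    cluster_geneset_enrichment,
    correlation_matrix,
    find_seed_cluster,
)
from .diffexp import wilcoxon_de
from .enrichment import score_candidates, selected_candidates
from .types import ValidationError, normalize_log

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Fixed analysis constants default to the published choices: six
    co-expression clusters, seed receptors KDR and FLT1, angiogenesis set
    GO:0001525.
    """

    expression_path: str
    network_path: str
    gene_sets_path: str
    candidates_path: str
    out_dir: str
    expression_format: str = "mtx10x"
    expression_normalized: bool = False
    labels_path: str | None = None
    markers_path: str | None = None
    target_cell_type: str = "endothelial"
    normalization_scale: float = 10_000.0
    de_alpha: float = 0.05
    lfc_min: float = 0.25
    selection_alpha: float = 0.05
    correlation_method: str = "spearman"
    cell_scope: str = "target_type"
    k: int = 6
    linkage: str = "average"
    seed_genes: list[str] = field(default_factory=lambda: ["KDR", "FLT1"])
    gene_set_id: str = "GO:0001525"
    universe_policy: str = "clustered_genes"
    summary_genes: list[str] = field(
        default_factory=lambda: ["LIF", "LIFR", "IL6ST", "IL6R", "KDR"]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "selection_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.lfc_min < 0:
            raise ValidationError("lfc_min must be >= 0")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.universe_policy not in ("clustered_genes", "scored_candidates"):
            raise ValidationError(f"unknown universe_policy {self.universe_policy!r}")
        if self.labels_path is None and self.markers_path is None:
            raise ValidationError("provide labels_path or markers_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        required = [self.expression_path, self.network_path,
                    self.gene_sets_path, self.candidates_path]
        required += [p for p in (self.labels_path, self.markers_path) if p]
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input file(s): {missing}")


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(self.format(record))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute every stage in order and write the TSV reports.

    Returns a mapping report-name -> written path. The manifest is written
    both on success and on handled (validation/format) failure, recording
    the failed stage. When fewer than two candidates pass selection the
    clustering stages are skipped with a warning rather than aborting.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "version": __version__,
        "stages": {},
        "warnings": [],
        "status": "running",
    }
    collector = _WarningCollector()
    logging.getLogger("receptornet").addHandler(collector)
    reports: dict[str, str] = {}
    stage = "setup"

    def finish_stage(name: str, t0: float, n_rows: int | None = None):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **({"rows": n_rows} if n_rows is not None else {}),
        }

    try:
        stage = "load_inputs"
        t0 = time.perf_counter()
        config.validate_paths()
        expr = rio.read_expression(
            config.expression_path,
            fmt=config.expression_format,
            normalized_flag=config.expression_normalized,
        )
        network = rio.read_network(config.network_path)
        gene_sets = rio.read_gmt(config.gene_sets_path)
        candidates = rio.read_candidates(config.candidates_path)
        finish_stage(stage, t0, expr.n_cells)

        stage = "normalize"
        t0 = time.perf_counter()
        if not expr.normalized:
            expr = normalize_log(expr, scale=config.normalization_scale)
        finish_stage(stage, t0, expr.n_cells)

        stage = "celltype"
        t0 = time.perf_counter()
        if config.labels_path:
            labels = rio.read_labels(config.labels_path)
            labels.validate_against(expr)
        else:
            markers = rio.read_markers(config.markers_path)
            labels = assign_cell_types(expr, markers)
        rio.write_labels(labels, out / "labels.tsv")
        reports["labels"] = str(out / "labels.tsv")
        finish_stage(stage, t0, len(labels.labels))

        stage = "differential_expression"
        t0 = time.perf_counter()
        de_table = wilcoxon_de(expr, labels, config.target_cell_type,
                               alpha=config.de_alpha, lfc_min=config.lfc_min)
        _write_tsv(de_table, out / "de_table.tsv")
        reports["de_table"] = str(out / "de_table.tsv")
        finish_stage(stage, t0, len(de_table))

        stage = "score_candidates"
        t0 = time.perf_counter()
        enr_table = score_candidates(network, de_table, set(expr.gene_ids),
                                     candidates, config.selection_alpha)
        _write_tsv(enr_table, out / "receptor_enrichment.tsv")
        reports["receptor_enrichment"] = str(out / "receptor_enrichment.tsv")
        finish_stage(stage, t0, len(enr_table))

        selected = selected_candidates(enr_table)
        if len(selected) >= 2:
            stage = "correlation"
            t0 = time.perf_counter()
            corr = correlation_matrix(
                expr, selected, labels=labels, cell_scope=config.cell_scope,
                target_type=config.target_cell_type,
                method=config.correlation_method,
            )
            corr_df = pd.DataFrame(corr.matrix, index=corr.genes,
                                   columns=corr.genes)
            corr_df.index.name = "gene"
            corr_df.to_csv(out / "correlation_matrix.tsv", sep="\t",
                           float_format=_FLOAT_FMT)
            reports["correlation_matrix"] = str(out / "correlation_matrix.tsv")
            finish_stage(stage, t0, len(corr.genes))

            stage = "cluster"
            t0 = time.perf_counter()
            k = min(config.k, len(corr.genes))
            if k < config.k:
                logger.warning("k reduced from %d to %d (only %d genes)",
                               config.k, k, len(corr.genes))
            assignment = agglomerative_cluster(corr, k=k,
                                               linkage_method=config.linkage)
            clusters_df = pd.DataFrame(
                {"gene": list(assignment.assignment),
                 "cluster": [assignment.assignment[g]
                             for g in assignment.assignment]}
            )
            _write_tsv(clusters_df, out / "clusters.tsv")
            reports["clusters"] = str(out / "clusters.tsv")
            finish_stage(stage, t0, len(clusters_df))

            stage = "seed_cluster_enrichment"
            t0 = time.perf_counter()
            seed_cluster = find_seed_cluster(assignment, config.seed_genes)
            universe = (None if config.universe_policy == "clustered_genes"
                        else list(candidates))
            results = []
            set_ids = ([config.gene_set_id] if config.gene_set_id in gene_sets.sets
                       else list(gene_sets))
            for sid in set_ids:
                res = cluster_geneset_enrichment(
                    assignment, seed_cluster, gene_sets[sid], gene_set_id=sid,
                    universe=universe,
                )
                results.append(asdict(res))
            enr_df = pd.DataFrame(results)
            _write_tsv(enr_df, out / "cluster_enrichment.tsv")
            reports["cluster_enrichment"] = str(out / "cluster_enrichment.tsv")
            finish_stage(stage, t0, len(enr_df))
        else:
            logger.warning(
                "only %d candidate(s) selected; clustering stages skipped",
                len(selected),
            )
            manifest["stages"]["cluster"] = {"skipped": True}

        stage = "summaries"
        t0 = time.perf_counter()
        wanted = [g for g in config.summary_genes if g.upper() in expr.gene_ids]
        if not wanted:
            wanted = selected[:5] if selected else expr.gene_ids[:5]
        summary = summarize_expression(expr, labels, wanted)
        _write_tsv(summary, out / "expression_summary.tsv")
        reports["expression_summary"] = str(out / "expression_summary.tsv")
        finish_stage(stage, t0, len(summary))

        manifest["status"] = "ok"
        return reports
    except (ValidationError, rio.FormatError) as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        raise
    finally:
        logging.getLogger("receptornet").removeHandler(collector)
        manifest["warnings"] = collector.records
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        reports["manifest"] = str(out / "manifest.json")
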