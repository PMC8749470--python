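"""Planted-truth synthetic datasets for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:
multiple cell types with elevated marker genes, a set of genes upregulated
only in the target (endothelial) type, candidate receptors whose network
neighborhoods are enriched for those genes (true receptors) or not
(decoys), latent-factor co-expression modules among the true receptors in
target-type cells, and a gene-set annotation covering exactly one module.

Counts are negative binomial, parameterized by mean and dispersion
(var = mu + dispersion * mu^2) and sampled as a gamma-Poisson mixture; the
module factors act multiplicatively on the mean (additively on log scale).
The interaction network is an Erdős–Rényi background over non-receptor
genes with each receptor's neighborhood wired explicitly, so neighborhood
composition is the only signal separating true receptors from decoys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import log
from pathlib import Path

import numpy as np

from . import io as rio
from .types import (
    CandidateList,
    CellTypeLabels,
    ExpressionMatrix,
    GeneNetwork,
    GeneSetCollection,
    ValidationError,
)

LN2 = log(2.0)


def _default_cells() -> dict[str, int]:
    return {
        "endothelial": 400,
        "pericyte": 400,
        "fibroblast": 400,
        "macrophage": 400,
        "RPE": 400,
    }


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are desk-scale study conditions."""

    n_cells_per_type: dict[str, int] = field(default_factory=_default_cells)
    target_type: str = "endothelial"
    n_genes: int = 2000
    n_marker_genes_per_type: int = 10
    marker_log2fc: float = 3.0
    n_de_genes: int = 100
    de_log2fc: float = 1.0
    nb_dispersion: float = 0.5
    n_true_receptors: int = 15
    n_decoy_receptors: int = 45
    neighborhood_size: int = 20
    neighborhood_de_fraction_true: float = 0.5
    neighborhood_de_fraction_decoy: float = 0.05
    background_mean_degree: float = 2.0
    mean_library_size: float = 2200.0
    library_size_sd: float = 0.3
    n_modules: int = 3
    module_factor_sd: float = 1.0
    annotated_module_index: int = 0
    annotated_set_id: str = "GO:0001525"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_cells_per_type or any(
            v <= 0 for v in self.n_cells_per_type.values()
        ):
            raise ValidationError("cell counts must be positive")
        if self.target_type not in self.n_cells_per_type:
            raise ValidationError(f"target type {self.target_type!r} not simulated")
        for name in ("neighborhood_de_fraction_true", "neighborhood_de_fraction_decoy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.de_log2fc < 0:
            raise ValidationError("de_log2fc must be >= 0")
        if not 0 <= self.annotated_module_index < self.n_modules:
            raise ValidationError("annotated_module_index out of range")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.mean_library_size <= 0 or self.library_size_sd < 0:
            raise ValidationError("library size parameters out of range")
        n_special = (
            len(self.n_cells_per_type) * self.n_marker_genes_per_type
            + self.n_de_genes
            + self.n_true_receptors
            + self.n_decoy_receptors
        )
        if n_special > self.n_genes:
            raise ValidationError(
                f"{n_special} structured genes exceed n_genes={self.n_genes}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    de_genes: list[str]
    true_receptors: list[str]
    decoy_receptors: list[str]
    receptor_module: dict[str, int]
    annotated_set_id: str
    marker_table: dict[str, list[str]]
    seed_genes: list[str]
    target_type: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["receptor_module"] = {k: int(v) for k, v in d["receptor_module"].items()}
        return cls(**d)


def simulate_dataset(params: SimulationParams):
    """Draw one dataset; identical params (incl. seed) give identical output.

    Returns (ExpressionMatrix raw counts, CellTypeLabels, GeneNetwork,
    GeneSetCollection, CandidateList, SyntheticTruth).
    """
    rng = np.random.default_rng(params.seed)
    types = list(params.n_cells_per_type)
    n_types = len(types)
    G = params.n_genes

    # --- gene layout: markers | DE | true receptors | decoys | background
    names = [f"G{i:04d}" for i in range(G)]
    cursor = 0
    marker_idx: dict[str, list[int]] = {}
    for t in types:
        marker_idx[t] = list(range(cursor, cursor + params.n_marker_genes_per_type))
        cursor += params.n_marker_genes_per_type
    de_idx = list(range(cursor, cursor + params.n_de_genes))
    cursor += params.n_de_genes
    true_idx = list(range(cursor, cursor + params.n_true_receptors))
    cursor += params.n_true_receptors
    decoy_idx = list(range(cursor, cursor + params.n_decoy_receptors))
    cursor += params.n_decoy_receptors
    background_idx = list(range(cursor, G))

    # modules over true receptors, round-robin blocks; seed receptors named
    # after the VEGF receptors so downstream defaults work out of the box
    receptor_module: dict[int, int] = {}
    per_module = max(1, params.n_true_receptors // params.n_modules)
    for j, gi in enumerate(true_idx):
        receptor_module[gi] = min(j // per_module, params.n_modules - 1)
    annotated = [gi for gi, m in receptor_module.items()
                 if m == params.annotated_module_index]
    seed_names = ["KDR", "FLT1"]
    for gi, nm in zip(annotated[:2], seed_names):
        names[gi] = nm

    # --- baseline means; receptors kept at moderate abundance so their
    # co-expression is observable
    base = rng.lognormal(mean=log(0.8), sigma=0.8, size=G)
    receptor_all = true_idx + decoy_idx
    base[receptor_all] = rng.uniform(1.0, 3.0, size=len(receptor_all))

    # --- per-cell log-mean and NB sampling
    cells_per_type = [params.n_cells_per_type[t] for t in types]
    n_cells = sum(cells_per_type)
    cell_ids = []
    cell_type_of = []
    for t in types:
        for i in range(params.n_cells_per_type[t]):
            cell_ids.append(f"{t}_{i:04d}")
            cell_type_of.append(t)

    log_mu = np.tile(np.log(base), (n_cells, 1))
    row = 0
    for t, nt in zip(types, cells_per_type):
        rows = slice(row, row + nt)
        log_mu[rows, marker_idx[t]] += params.marker_log2fc * LN2
        if t == params.target_type:
            log_mu[rows, de_idx] += params.de_log2fc * LN2
            # mean-centered on the count scale (E[exp(z)] = 1) so modules add
            # co-variation without systematic up-regulation
            sd = params.module_factor_sd
            z = rng.normal(-0.5 * sd * sd, sd, size=(nt, params.n_modules))
            for gi, m in receptor_module.items():
                log_mu[rows, gi] += z[:, m]
        row += nt

    # Per-cell expected profiles are rescaled to a library size drawn
    # independently of cell type (sequencing depth is technical), so
    # type-specific up-regulation changes composition, not depth.
    mu = np.exp(log_mu)
    depth = params.mean_library_size * rng.lognormal(
        -0.5 * params.library_size_sd**2, params.library_size_sd, size=n_cells
    )
    mu *= (depth / mu.sum(axis=1))[:, None]

    r = 1.0 / params.nb_dispersion  # NB size parameter
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(float)

    expr = ExpressionMatrix(cell_ids=cell_ids, gene_ids=names, values=counts,
                            normalized=False)
    labels = CellTypeLabels(labels=dict(zip(cell_ids, cell_type_of)))

    # --- network: explicit receptor neighborhoods + ER background
    nonde_pool = np.array(background_idx)
    if params.neighborhood_size > len(nonde_pool) or (
        params.neighborhood_size > len(de_idx)
        and params.neighborhood_de_fraction_true == 1.0
    ):
        raise ValidationError("neighborhood_size exceeds available non-receptor genes")
    edges: list[tuple[str, str]] = []
    de_arr = np.array(de_idx)
    for gi in true_idx + decoy_idx:
        frac = (params.neighborhood_de_fraction_true if gi in receptor_module
                else params.neighborhood_de_fraction_decoy)
        n_de = int(round(params.neighborhood_size * frac))
        n_bg = params.neighborhood_size - n_de
        if n_de > len(de_arr) or n_bg > len(nonde_pool):
            raise ValidationError("neighborhood_size exceeds available pool genes")
        picks = list(rng.choice(de_arr, size=n_de, replace=False))
        picks += list(rng.choice(nonde_pool, size=n_bg, replace=False))
        edges.extend((names[gi], names[int(p)]) for p in picks)

    # ER background among non-receptor genes
    non_receptor = [i for i in range(G) if i not in set(receptor_all)]
    p_bg = min(1.0, params.background_mean_degree / max(1, len(non_receptor) - 1))
    n_possible = len(non_receptor) * (len(non_receptor) - 1) // 2
    n_bg_edges = rng.binomial(n_possible, p_bg)
    ii = rng.integers(0, len(non_receptor), size=2 * n_bg_edges)
    jj = rng.integers(0, len(non_receptor), size=2 * n_bg_edges)
    added = 0
    for a, b in zip(ii, jj):
        if added >= n_bg_edges:
            break
        if a != b:
            edges.append((names[non_receptor[a]], names[non_receptor[b]]))
            added += 1
    network = GeneNetwork.from_edges(edges)

    gene_sets = GeneSetCollection(
        sets={params.annotated_set_id: {names[gi] for gi in annotated}},
        descriptions={params.annotated_set_id: "angiogenesis"},
    )
    candidates = CandidateList(
        symbols=[names[gi] for gi in receptor_all],
        roles={names[gi]: "receptor" for gi in receptor_all},
    )
    truth = SyntheticTruth(
        de_genes=[names[gi] for gi in de_idx],
        true_receptors=[names[gi] for gi in true_idx],
        decoy_receptors=[names[gi] for gi in decoy_idx],
        receptor_module={names[gi]: m for gi, m in receptor_module.items()},
        annotated_set_id=params.annotated_set_id,
        marker_table={t: [names[gi] for gi in marker_idx[t]] for t in types},
        seed_genes=seed_names,
        target_type=params.target_type,
    )
    return expr, labels, network, gene_sets, candidates, truth


def write_dataset(out_dir: str | Path, params: SimulationParams,
                  fmt: str = "mtx10x") -> SyntheticTruth:
    """Simulate and write every artifact in the pipeline's input dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, labels, network, gene_sets, candidates, truth = simulate_dataset(params)
    if fmt == "mtx10x":
        rio.write_expression(expr, out / "expression", fmt="mtx10x")
    else:
        rio.write_expression(expr, out / "expression.tsv", fmt="dense_tsv")
    rio.write_labels(labels, out / "labels.tsv")
    rio.write_network(network, out / "network.tsv")
    rio.write_gmt(gene_sets, out / "gene_sets.gmt")
    rio.write_candidates(candidates, out / "candidates.tsv")
    rio.write_markers({t: set(g) for t, g in truth.marker_table.items()},
                      out / "markers.tsv")
    truth.to_json(out / "truth.json")
    return truth
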