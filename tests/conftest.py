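import numpy as np
import pytest

from receptornet.synthetic import SimulationParams
from receptornet.types import CellTypeLabels, ExpressionMatrix


def make_expr(values, normalized=True, cell_ids=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(
        cell_ids=cell_ids or [f"cell{i}" for i in range(n)],
        gene_ids=gene_ids or [f"GENE{j}" for j in range(g)],
        values=values,
        normalized=normalized,
    )


def two_group_labels(expr, n_target, target="target", rest="rest"):
    return CellTypeLabels(labels={
        c: (target if i < n_target else rest)
        for i, c in enumerate(expr.cell_ids)
    })


@pytest.fixture(scope="session")
def small_params():
    """Reduced-scale simulation for fast structural/property tests."""
    return SimulationParams(
        n_cells_per_type={"endothelial": 150, "pericyte": 150, "fibroblast": 150},
        n_genes=500,
        n_marker_genes_per_type=5,
        n_de_genes=40,
        n_true_receptors=6,
        n_decoy_receptors=12,
        neighborhood_size=10,
        n_modules=2,
        seed=7,
    )
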