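"""Target-vs-rest differential expression on normalized single-cell data.

The per-gene test is a two-sided Wilcoxon rank-sum: exact enumeration over
rank assignments when both groups have at most eight cells, otherwise the
tie-corrected normal approximation with continuity correction.  Fold change
is computed on de-logged group means with a pseudocount of 1, and the
Benjamini-Hochberg step-up controls the FDR across genes.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CellTypeLabels, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

EXACT_MAX_N = 8  # both groups at or below this size -> exact enumeration


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumeration of rank assignments.

    Uses midranks, so ties are handled exactly. p = min(1, 2 * min tail),
    with the observed statistic included in both tails. Cost is
    C(n1+n2, n1) sums; intended for n1, n2 <= 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n = len(x), len(x) + len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    eps = 1e-9
    n_le = n_ge = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    total = comb(n, n1)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def _normal_approx_p(ranks: np.ndarray, t_mask: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal approximation, one p per gene column."""
    n = ranks.shape[0]
    n1 = int(t_mask.sum())
    n2 = n - n1
    w = ranks[t_mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # tie term sum(t^3 - t) per gene
    tie = np.empty(ranks.shape[1])
    for j in range(ranks.shape[1]):
        _, counts = np.unique(ranks[:, j], return_counts=True)
        tie[j] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    p = np.ones(ranks.shape[1])
    ok = sigma2 > 0
    z = (np.abs(w[ok] - mu) - 0.5) / np.sqrt(sigma2[ok])
    z = np.maximum(z, 0.0)  # continuity correction must not cross the mean
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return p


def wilcoxon_de(
    expr: ExpressionMatrix,
    labels: CellTypeLabels,
    target_type: str,
    alpha: float = 0.05,
    lfc_min: float = 0.25,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE of ``target_type`` cells versus the rest.

    Returns a DataFrame with columns gene, log2_fold_change, p_value, fdr,
    is_de (fdr < alpha and |log2FC| >= lfc_min). Fold change is
    log2((mean(expm1(target)) + 1) / (mean(expm1(rest)) + 1)). Genes constant
    across both groups get p = 1 by convention.
    """
    if not expr.normalized:
        raise ValidationError("differential expression requires normalized values")
    labels.validate_against(expr)
    cell_to_type = labels.labels
    labeled = [i for i, c in enumerate(expr.cell_ids) if c in cell_to_type]
    t_mask = np.array(
        [cell_to_type[expr.cell_ids[i]] == target_type for i in labeled], dtype=bool
    )
    if not t_mask.any():
        raise ValidationError(f"target type {target_type!r} has no labeled cells")
    n1, n2 = int(t_mask.sum()), int((~t_mask).sum())
    if n1 < 3 or n2 < 3:
        raise ValidationError(
            f"need >=3 cells per group, got target={n1}, rest={n2}"
        )
    X = expr.values[labeled]

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        p = np.array(
            [exact_rank_sum_p(X[t_mask, j], X[~t_mask, j]) for j in range(X.shape[1])]
        )
        constant = np.array([np.ptp(X[:, j]) == 0 for j in range(X.shape[1])])
        p[constant] = 1.0
    else:
        ranks = stats.rankdata(X, axis=0)
        p = _normal_approx_p(ranks, t_mask)

    n_const = int(np.sum(np.ptp(X, axis=0) == 0))
    if n_const:
        logger.info("%d constant gene(s): p set to 1", n_const)

    mean_t = np.expm1(X[t_mask]).mean(axis=0)
    mean_r = np.expm1(X[~t_mask]).mean(axis=0)
    lfc = np.log2((mean_t + 1.0) / (mean_r + 1.0))

    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": fdr,
            "is_de": (fdr < alpha) & (np.abs(lfc) >= lfc_min),
        }
    )
    return table


def de_gene_set(de_table: pd.DataFrame) -> set[str]:
    """Genes flagged differentially expressed."""
    return set(de_table.loc[de_table["is_de"], "gene"])
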