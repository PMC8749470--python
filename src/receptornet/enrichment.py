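"""Network-neighborhood enrichment of candidate receptors/TFs.

Each candidate is scored by the hypergeometric over-representation of
differentially expressed genes among its direct network neighbors, with the
universe restricted to genes observable by both evidence sources (present in
the expression matrix and the network) minus the candidate itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust, de_gene_set
from .types import CandidateList, GeneNetwork, ValidationError

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed via the numerically stable survival function; exact 1.0 at
    k = 0 and when the draw exhausts the universe (n = N, k = K).
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(
            f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def score_candidates(
    network: GeneNetwork,
    de_table: pd.DataFrame,
    expr_genes: set[str],
    candidates: CandidateList,
    selection_alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every candidate's neighborhood for DE-gene enrichment.

    For candidate c the universe is (expr_genes ∩ network nodes) \\ {c};
    draws are c's neighbors within the universe, successes the DE genes in
    the universe. Candidates whose in-universe neighborhood is empty are
    reported with p = 1 and excluded from the BH adjustment.

    Returns columns: candidate, neighborhood_size_in_universe, de_overlap,
    p_value, fdr, selected.
    """
    expr_genes = {g.upper() for g in expr_genes}
    base_universe = expr_genes & network.nodes
    if not base_universe:
        raise ValidationError("universe is empty: expression and network share no genes")
    de_genes = de_gene_set(de_table) & expr_genes

    rows = []
    for cand in candidates:
        universe = base_universe - {cand}
        neigh = network.neighbors(cand) & universe
        de_in_universe = de_genes & universe
        k = len(neigh & de_in_universe)
        n = len(neigh)
        if n == 0:
            rows.append((cand, 0, 0, 1.0, False))
            continue
        p = hypergeom_upper_tail(k, len(de_in_universe), n, len(universe))
        rows.append((cand, n, k, p, True))

    df = pd.DataFrame(
        rows,
        columns=["candidate", "neighborhood_size_in_universe", "de_overlap",
                 "p_value", "_scored"],
    )
    n_unscored = int((~df["_scored"]).sum())
    if n_unscored:
        logger.warning(
            "%d candidate(s) have no in-universe neighbors; p = 1, "
            "excluded from BH", n_unscored,
        )
    fdr = np.ones(len(df))
    scored = df["_scored"].to_numpy()
    if scored.any():
        fdr[scored] = bh_adjust(df.loc[scored, "p_value"].to_numpy())
    df["fdr"] = fdr
    df["selected"] = df["fdr"] < selection_alpha
    return df.drop(columns="_scored")


def selected_candidates(table: pd.DataFrame) -> list[str]:
    """Candidates passing the FDR selection threshold, input order preserved."""
    return list(table.loc[table["selected"], "candidate"])
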