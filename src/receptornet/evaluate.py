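"""Planted-truth evaluation metrics for synthetic runs.

The observed FDR follows the standard benchmark definition: the fraction
of flagged genes that are truly null. Marker genes are genuinely
differential by construction (elevated in their own cell type, hence
shifted in any target-vs-rest contrast), and receptor expression in the
target type carries the latent module factor, so flagging them is not an
error; only flagged background genes count as false discoveries. Recall
is measured on the planted target-type DE set alone.
"""

from __future__ import annotations

from math import comb

import pandas as pd

from .synthetic import SyntheticTruth


def de_recall_and_fdr(de_table: pd.DataFrame, truth: SyntheticTruth):
    """(recall of planted DE genes, observed FDR among flagged genes)."""
    flagged = set(de_table.loc[de_table["is_de"], "gene"])
    planted = set(truth.de_genes)
    non_null = planted | set(truth.true_receptors) | set(truth.decoy_receptors)
    non_null |= {g for gs in truth.marker_table.values() for g in gs}
    recall = len(flagged & planted) / len(planted) if planted else float("nan")
    fdr = (len(flagged - non_null) / len(flagged)) if flagged else 0.0
    return recall, fdr


def receptor_selection_metrics(enrichment_table: pd.DataFrame,
                               truth: SyntheticTruth):
    """(number of true receptors selected, number of decoys selected)."""
    selected = set(enrichment_table.loc[enrichment_table["selected"], "candidate"])
    return (len(selected & set(truth.true_receptors)),
            len(selected & set(truth.decoy_receptors)))


def adjusted_rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """ARI between two clusterings given as item -> cluster-id mappings.

    Computed on the shared items from the pair-counting contingency table;
    returns 1.0 for identical partitions, ~0 for independent ones.
    """
    items = sorted(set(labels_a) & set(labels_b))
    if not items:
        raise ValueError("no shared items between clusterings")
    table: dict[tuple, int] = {}
    row_tot: dict = {}
    col_tot: dict = {}
    for it in items:
        a, b = labels_a[it], labels_b[it]
        table[(a, b)] = table.get((a, b), 0) + 1
        row_tot[a] = row_tot.get(a, 0) + 1
        col_tot[b] = col_tot.get(b, 0) + 1
    n = len(items)
    sum_cells = sum(comb(v, 2) for v in table.values())
    sum_rows = sum(comb(v, 2) for v in row_tot.values())
    sum_cols = sum(comb(v, 2) for v in col_tot.values())
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


def label_accuracy(predicted: dict[str, str], truth_labels: dict[str, str]) -> float:
    shared = set(predicted) & set(truth_labels)
    if not shared:
        raise ValueError("no shared cells")
    return sum(predicted[c] == truth_labels[c] for c in shared) / len(shared)
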