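"""Hypergeometric overrepresentation analysis of LOY-associated genes.

Significant DE genes passing a direction and log-fold-change cutoff are
tested for enrichment in each gene set by the upper-tail hypergeometric
test (equivalent to a one-tailed Fisher's exact test), against a universe
of the genes that entered the DE run.  BH-FDR is applied across sets
within one (direction, cutoff) family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ora", "select_de_genes"]

LOGFC_CUTOFFS = (0.25, 0.5, 0.75)


def select_de_genes(de_table: pd.DataFrame, direction: str, cutoff: float,
                    alpha: float = 0.05) -> list:
    """Significant genes passing the direction/log2FC cutoff."""
    if direction == "up":
        mask = de_table["avg_log2fc"] > cutoff
    elif direction == "down":
        mask = de_table["avg_log2fc"] < -cutoff
    else:
        raise ValueError("direction must be 'up' or 'down'")
    mask &= de_table["p_adj"] < alpha
    return list(de_table.loc[mask, "gene"])


def ora(de_table: pd.DataFrame, gene_sets: dict[str, set], direction: str = "up",
        cutoff: float = 0.25, alpha: float = 0.05,
        universe=None, selected=None) -> pd.DataFrame:
    """Overrepresentation of selected DE genes in each gene set.

    ``universe`` defaults to the genes tested in the DE run (the table's
    gene column) and ``selected`` to the significant genes passing the
    direction/cutoff filter.  Per set with members in the universe, the
    p-value is ``P(overlap >= observed)`` under the hypergeometric law;
    overlap_ratio uses the in-universe set size as denominator.
    """
    universe = set(universe) if universe is not None else set(de_table["gene"])
    if selected is None:
        selected = select_de_genes(de_table, direction, cutoff, alpha)
    selected = set(selected) & universe
    M, n_sel = len(universe), len(selected)

    rows = []
    for name, members in gene_sets.items():
        in_univ = set(members) & universe
        if not in_univ:
            continue  # set absent from the tested universe
        K = len(in_univ)
        k = len(in_univ & selected)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, K, n_sel))
        rows.append({
            "set_name": name, "direction": direction, "logfc_cutoff": cutoff,
            "n_selected": n_sel, "set_size": K, "n_overlap": k,
            "overlap_ratio": k / K, "p_hypergeometric": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p_hypergeometric"], method="fdr_bh")[1]
    return out
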