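"""Hypergeometric over-representation of a signature in gene sets.

For each set, with N universe genes, K of them in the set, n signature
genes and k in the overlap, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n); Benjamini-Hochberg adjustment is
applied across all tested sets. Only over-representation is tested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection, GeneSignature
from .diffexpr import benjamini_hochberg

__all__ = ["hypergeom_enrich", "report_overlaps"]


def hypergeom_enrich(
    signature: GeneSignature,
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Per-set over-representation table, sorted by adjusted p then name.

    Signature genes outside the universe are dropped with a warning; gene
    sets are intersected with the universe before testing.
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise ValueError("empty gene universe")
    sig_genes = [g for g in signature.gene_ids if g in universe]
    outside = len(signature.gene_ids) - len(sig_genes)
    if outside:
        warnings.warn(
            f"{outside} signature gene(s) outside the universe were dropped"
        )
    sig_set = set(sig_genes)
    n_universe = len(universe)
    n_sig = len(sig_set)

    rows = []
    for gene_set in sets:
        members = gene_set.gene_ids & universe
        overlap = sorted(members & sig_set)
        k = len(overlap)
        big_k = len(members)
        # P(X >= k) under Hypergeometric(N, K, n)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_sig))
        rows.append(
            {
                "set_name": gene_set.name,
                "k": k,
                "K": big_k,
                "n": n_sig,
                "N": n_universe,
                "p_value": min(1.0, p),
                "overlap_genes": ",".join(overlap),
            }
        )
    frame = pd.DataFrame(rows).set_index("set_name")
    frame["adj_p"] = benjamini_hochberg(frame["p_value"].to_numpy())
    frame = frame.sort_values(by=["adj_p", "set_name"], kind="stable")
    return frame


def report_overlaps(result: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant sets (adj_p < alpha) with their overlap gene lists."""
    hits = result[result["adj_p"] < alpha].copy()
    if hits.empty:
        warnings.warn(f"no gene set passes adj_p < {alpha}")
    return hits[["adj_p", "overlap_genes", "k", "K"]]
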