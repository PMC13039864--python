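"""Gene-set over-representation: one-sided hypergeometric test with BH FDR.

A desk-scale replacement for a web over-representation service (GO BP via
g:Profiler in the original workflow): each set in a GMT collection is
tested for over-representation in a query gene list against a background
universe (by default, all detected genes) with the hypergeometric upper
tail P[X >= k], and q-values are Benjamini-Hochberg adjusted across all
tested sets.  BH is a deliberate, documented substitution for g:Profiler's
proprietary g:SCS correction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, normalize_symbol

__all__ = ["hypergeom_p", "enrich"]


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts the overlap between a size-n draw (the query) and a size-K
    marked subset (the gene set) from a universe of N genes.
    """
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``collection``.

    Returns one row per set that intersects the background, sorted by
    p-value (ties broken by set name), with columns set_name, set_size,
    query_size, overlap, background_size, p_value, q_value and the
    overlapping symbols.  Query genes outside the background are dropped;
    their count is in ``result.attrs["n_query_dropped"]``.
    """
    bg = {normalize_symbol(g) for g in background}
    if not bg:
        raise ValueError("empty background universe")
    raw_query = {normalize_symbol(g) for g in query}
    q = raw_query & bg
    n_dropped = len(raw_query) - len(q)

    N, n = len(bg), len(q)
    rows = []
    for name, gs in sorted(collection, key=lambda item: item[0]):
        members = gs.members & bg
        if not members:
            continue
        overlap = sorted(members & q)
        K, k = len(members), len(overlap)
        rows.append(
            {
                "set_name": name,
                "set_size": K,
                "query_size": n,
                "overlap": k,
                "background_size": N,
                "p_value": hypergeom_p(k, K, n, N),
                "overlap_genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "set_size",
            "query_size",
            "overlap",
            "background_size",
            "p_value",
            "overlap_genes",
        ],
    )
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(
            ["p_value", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["q_value"] = pd.Series(dtype=float)
    table = table[
        [
            "set_name",
            "set_size",
            "query_size",
            "overlap",
            "background_size",
            "p_value",
            "q_value",
            "overlap_genes",
        ]
    ]
    table.attrs["n_query_dropped"] = n_dropped
    return table
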