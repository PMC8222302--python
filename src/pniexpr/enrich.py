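"""Hypergeometric over-representation analysis of DEG lists.

For each gene set, with universe size N (here: the endogenous codeset),
set size K (after intersecting with the universe), query size n and
overlap k, the enrichment p-value is the inclusive upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

adjusted across sets with Benjamini-Hochberg.  Query genes outside the
universe are dropped with a warning; sets with no universe overlap are
skipped.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .diffexpr import adjust_bh


def hypergeometric_ora(query_genes, collection: GeneSetCollection,
                       universe_genes) -> pd.DataFrame:
    """Test every gene set for over-representation of the query.

    Returns a table (one row per tested set, sorted by adjusted p) with
    columns set_name, k (overlap), K (set size in universe), n (query size
    in universe), N (universe size), p_raw, p_adj and the overlapping genes.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2)
        query &= universe
        if not query:
            raise ValueError("no query genes remain within the universe")

    N = len(universe)
    n = len(query)
    rows = []
    for set_id, members in collection:
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        overlap = in_universe & query
        k = len(overlap)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set_id": set_id,
            "set_name": collection.names.get(set_id, set_id),
            "k": k, "K": K, "n": n, "N": N,
            "p_raw": p_raw,
            "genes": ";".join(sorted(overlap)),
        })
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p_raw", "p_adj", "genes"]
        ).rename_axis("set_id")
    table = pd.DataFrame(rows).set_index("set_id")
    table["p_adj"] = adjust_bh(table["p_raw"])
    table = table.sort_values(["p_adj", "p_raw", "set_id"], kind="mergesort")
    return table[["set_name", "k", "K", "n", "N", "p_raw", "p_adj", "genes"]]


def top_sets(table: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Most significant ``n`` sets — the shape of a top-pathways dot plot."""
    return table.head(n)
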