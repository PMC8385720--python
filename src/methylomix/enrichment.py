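"""Over-representation analysis of gene lists against GMT collections.

Each set is scored by the hypergeometric upper tail P(X >= k) for the
observed overlap k between the (deduplicated) query and the set, both
restricted to a finite gene universe, with Benjamini–Hochberg correction
across sets.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_tail", "ora"]


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed via the survival function in log-stable form; ``k = 0`` returns
    exactly 1.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """One row per gene set with overlap >= ``min_overlap``; BH over all tested sets.

    Query genes outside the universe are dropped (count logged); an empty
    query after intersection errors.  Columns: set, k, n, K, N, p, fdr,
    genes (comma-joined sorted overlap).
    """
    uni = set(universe)
    query = set(query_genes)
    dropped = len(query - uni)
    if dropped:
        logger.info("dropping %d query gene(s) outside the universe", dropped)
    query &= uni
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(uni), len(query)

    rows = []
    for gs in collection:
        members = gs.members & uni
        overlap = sorted(query & members)
        k, K = len(overlap), len(members)
        if K == 0:
            continue
        rows.append(
            {
                "set": gs.name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeom_tail(k, n, K, N),
                "genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p", "genes"])
    if df.empty:
        return df.assign(fdr=pd.Series(dtype=float))
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df = df[df["k"] >= min_overlap]
    return df.sort_values(["p", "set"]).reset_index(drop=True)[
        ["set", "k", "n", "K", "N", "p", "fdr", "genes"]
    ]
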