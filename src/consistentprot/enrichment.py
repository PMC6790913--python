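"""Hypergeometric over-representation analysis (ORA) with BH FDR.

Tests whether a query gene list (e.g. the consistently DOWN proteins)
overlaps a gene set more than expected by chance, given a universe of
N genes of which K belong to the set and n were queried:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

One-sided (over-representation only), with Benjamini–Hochberg control
across all tested sets.  The recommended universe is the post-filter
quantified proteome, not the whole genome.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["hypergeometric_tail_p", "bh_fdr", "ora"]


def hypergeometric_tail_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of drawing at
    least k set members when n genes are drawn from a universe of N
    containing K set members."""
    if not (0 <= k and 0 <= K <= N and 0 <= n <= N and k <= min(K, n)):
        raise ValueError(f"inconsistent arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query_genes: Iterable[str],
    sets: GeneSetCollection,
    universe_genes: Iterable[str],
    min_overlap: int = 0,
) -> pd.DataFrame:
    """Over-representation of a query list in each gene set.

    Gene identity is by upper-cased symbol.  Query genes outside the
    universe are dropped with a warning; each set is intersected with
    the universe before testing.  Rows are sorted by p ascending (ties
    by set name); ``q_bh`` is computed across all tested sets.  Sets
    with overlap below ``min_overlap`` are excluded before FDR control.
    """
    universe = {str(g).upper() for g in universe_genes if str(g).strip()}
    if not universe:
        raise ValueError("empty universe")
    query = {str(g).upper() for g in query_genes if str(g).strip()}
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped "
            f"(e.g. {sorted(outside)[:3]})"
        )
        query &= universe
        if not query:
            raise ValueError("no query genes remain inside the universe")

    N, n = len(universe), len(query)
    rows = []
    for s in sets:
        members = {m.upper() for m in s.members} & universe
        K = len(members)
        overlap = sorted(members & query)
        k = len(overlap)
        if k < min_overlap or K == 0:
            continue
        rows.append(
            {
                "set_name": s.name,
                "universe_size": N,
                "query_size": n,
                "set_size": K,
                "overlap": k,
                "p_hypergeom": hypergeometric_tail_p(k, K, n, N),
                "overlap_genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "universe_size", "query_size", "set_size",
            "overlap", "p_hypergeom", "overlap_genes",
        ],
    )
    if len(out):
        out["q_bh"] = bh_fdr(out["p_hypergeom"])
    else:
        out["q_bh"] = pd.Series(dtype=float)
    out = out.sort_values(["p_hypergeom", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
    return out[
        [
            "set_name", "universe_size", "query_size", "set_size",
            "overlap", "p_hypergeom", "q_bh", "overlap_genes",
        ]
    ]
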