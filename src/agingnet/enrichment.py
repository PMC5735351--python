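"""Gene-set over-representation analysis.

For a query of n genes drawn from a background of N, and a term covering
K background genes of which k overlap the query, the enrichment p-value
is the upper tail of the hypergeometric distribution,
P(X >= k), identical to a one-sided Fisher exact test on the 2x2 table.
The EASE variant (the conservative score popularized by the DAVID
platform) computes the same tail with one overlapping gene removed,
P(X >= k - 1 | K, n unchanged), and is >= the plain hypergeometric value
whenever k >= 1. Benjamini-Hochberg adjustment is applied across the
tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationCollection, canonical_symbol

HYPERGEOMETRIC = "hypergeometric"
EASE = "ease"


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # query genes in term
    n: int  # query size
    K: int  # term size within background
    N: int  # background size
    p_value: float
    p_adjusted: float
    method: str


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    annotations: AnnotationCollection,
    background: Iterable[str],
    method: str = HYPERGEOMETRIC,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in the query.

    The query must be a subset of the background; each term's gene set is
    intersected with the background before testing. Results come back
    sorted by ascending p-value (ties by term name).
    """
    if method not in (HYPERGEOMETRIC, EASE):
        raise ValueError(f"unknown method {method!r}")
    bg = frozenset(canonical_symbol(g) for g in background)
    if not bg:
        raise ValueError("background set is empty")
    q = frozenset(canonical_symbol(g) for g in query)
    stray = q - bg
    if stray:
        raise ValueError(
            f"query genes outside background: {', '.join(sorted(stray)[:10])}"
        )

    N, n = len(bg), len(q)
    raw: list[tuple[str, int, int, float]] = []
    for term in annotations:
        term_genes = annotations.genes(term) & bg
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & q)
        if method == EASE:
            p = hypergeom_tail(max(k - 1, 0), N, K, n) if k >= 1 else 1.0
        else:
            p = hypergeom_tail(k, N, K, n)
        raw.append((term, k, K, min(p, 1.0)))

    adjusted = bh_adjust([p for *_, p in raw]) if raw else []
    results = [
        EnrichmentResult(
            term=term, k=k, n=n, K=K, N=N, p_value=p, p_adjusted=p_adj, method=method
        )
        for (term, k, K, p), p_adj in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjusted p-values, order-preserving."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])
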