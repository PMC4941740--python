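"""Hypergeometric over-representation tests with Benjamini–Hochberg control.

One-sided upper-tail tests only: P(X >= k) when drawing ``n`` genes without
replacement from a universe of ``N`` containing ``K`` term members. The
universe strongly affects p-values and must be supplied explicitly.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_upper", "bh_adjust", "enrich", "read_gmt"]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Computed via the stable survival function; ``k=0`` returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got N={N} K={K} n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k} with K={K} n={n}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, each p_(i) is scaled by m/i, then monotonicity is
    enforced by a cumulative minimum from the largest rank; values are
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation test."""

    term: str
    N: int
    K: int
    n: int
    k: int
    p: float
    p_adj: float
    significant: bool


def enrich(query: AbstractSet[str], terms: Mapping[str, AbstractSet[str]],
           universe: AbstractSet[str], alpha: float = 0.01) -> list[EnrichmentResult]:
    """Test every term gene set for over-representation in the query.

    Query genes outside the universe are dropped with a warning; each term
    is intersected with the universe. Results are sorted by adjusted p and
    flagged significant at ``p_adj < alpha``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query_in = frozenset(query) & universe
    n_outside = len(frozenset(query)) - len(query_in)
    if n_outside:
        logger.warning("%d query genes outside the universe were dropped", n_outside)

    N, n = len(universe), len(query_in)
    raw = []
    meta = []
    for term, genes in terms.items():
        members = frozenset(genes) & universe
        k = len(members & query_in)
        raw.append(hypergeom_upper(N, len(members), n, k))
        meta.append((term, len(members), k))
    adjusted = bh_adjust(raw)
    results = [
        EnrichmentResult(term=term, N=N, K=K, n=n, k=k, p=p, p_adj=p_adj,
                         significant=p_adj < alpha)
        for (term, K, k), p, p_adj in zip(meta, raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.term))
    return results


def read_gmt(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """GMT gene sets: term, description, then member genes per tab-separated line."""
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs term, description and >= 1 gene")
            terms[fields[0]] = frozenset(g for g in fields[2:] if g)
    return terms
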