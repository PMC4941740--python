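"""Overlap of differential-expression tables with SNP candidate-gene sets.

The DEG table is a plain TSV with columns ``gene_id``, ``logfc`` and
``pvalue``. Matching against candidate sets is by case-folded gene symbol;
no orthology mapping is attempted, so cross-species comparisons inherit
whatever symbol concordance the inputs provide.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import AbstractSet, Sequence

import pandas as pd

from multicom._util import pct
from multicom.enrichment import hypergeom_upper

logger = logging.getLogger(__name__)

CATEGORIES = ("low_specific", "high_specific", "common")

__all__ = ["DEGRecord", "OverlapReport", "CategoryOverlap", "load_deg", "overlap_deg"]


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    logfc: float
    pvalue: float

    @property
    def direction(self) -> str:
        return "up" if self.logfc > 0 else "down"


def load_deg(path: str | os.PathLike, alpha: float = 0.01) -> list[DEGRecord]:
    """Load significant DEG rows (``pvalue < alpha``) from a TSV.

    Duplicate gene ids keep the smallest p-value; rows with zero logFC carry
    no direction and are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "logfc", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DEG columns: {sorted(missing)}")
    df = df.sort_values("pvalue", kind="stable").drop_duplicates("gene_id", keep="first")
    n_zero = int((df["logfc"] == 0).sum())
    if n_zero:
        logger.warning("%s: dropped %d rows with zero logFC (no direction)", path, n_zero)
    df = df[(df["logfc"] != 0) & (df["pvalue"] < alpha)]
    return [DEGRecord(str(r.gene_id), float(r.logfc), float(r.pvalue))
            for r in df.itertuples(index=False)]


@dataclass(frozen=True)
class CategoryOverlap:
    category: str
    n: int
    n_up: int
    n_down: int
    pvalue: float


@dataclass(frozen=True)
class OverlapReport:
    """Fig 4-shaped accounting of DEG vs candidate-gene categories."""

    n_deg: int
    n_up: int
    n_down: int
    categories: tuple[CategoryOverlap, ...]

    @property
    def total_overlap(self) -> int:
        return sum(c.n for c in self.categories)

    @property
    def overlap_fraction(self) -> float:
        """Share of DEG hit by any candidate category, % half-up 1dp."""
        return pct(self.total_overlap, self.n_deg) if self.n_deg else 0.0


def overlap_deg(degs: Sequence[DEGRecord], genes_low: AbstractSet[str],
                genes_high: AbstractSet[str], genes_common: AbstractSet[str],
                universe: AbstractSet[str]) -> OverlapReport:
    """Assign each DEG to at most one candidate category and test each overlap.

    The three candidate sets must be pairwise disjoint (they are by
    construction when derived from a group partition). Per-category
    significance is an upper-tail hypergeometric test against the supplied
    universe.
    """
    fold = lambda g: g.casefold()
    sets = {"low_specific": frozenset(map(fold, genes_low)),
            "high_specific": frozenset(map(fold, genes_high)),
            "common": frozenset(map(fold, genes_common))}
    for a in CATEGORIES:
        for b in CATEGORIES:
            if a < b and sets[a] & sets[b]:
                raise ValueError(f"candidate gene sets {a} and {b} are not disjoint")
    universe = frozenset(map(fold, universe))
    if not universe:
        raise ValueError("empty universe")

    deg_ids = {fold(d.gene_id): d for d in degs}
    deg_in_universe = frozenset(deg_ids) & universe
    n_deg = len(degs)
    n_up = sum(1 for d in degs if d.direction == "up")

    categories = []
    for name in CATEGORIES:
        members = sets[name]
        hit = frozenset(deg_ids) & members
        up = sum(1 for g in hit if deg_ids[g].direction == "up")
        K = len(members & universe)
        k_in = len(hit & universe)
        p = hypergeom_upper(len(universe), K, len(deg_in_universe), min(k_in, K, len(deg_in_universe)))
        categories.append(CategoryOverlap(category=name, n=len(hit), n_up=up,
                                          n_down=len(hit) - up, pvalue=p))

    report = OverlapReport(n_deg=n_deg, n_up=n_up, n_down=n_deg - n_up,
                           categories=tuple(categories))
    assert report.total_overlap == sum(c.n for c in categories)
    return report
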