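"""k-of-n reproducibility consensus over caller callsets.

A SNP is retained when at least ``min_support`` callers report it (default
2). The full Venn decomposition is computed alongside: per-tool totals,
pairwise intersections, the all-caller intersection, and the tool-specific
(support == 1) sets that the consensus discards as putative false positives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from multicom._util import round_half_up
from multicom.variants import Callset, VariantKey

__all__ = ["ConsensusResult", "multicom", "support_histogram", "discovery_gain"]


@dataclass
class ConsensusResult:
    """Outcome of a k-of-n consensus over one group's callsets."""

    group: str
    k: int
    callers: tuple[str, ...]
    per_tool_total: dict[str, int]
    pairwise: dict[frozenset, int]
    triple: int
    shared: frozenset[VariantKey]
    tool_specific: dict[str, frozenset[VariantKey]]
    support_histogram: dict[int, int]
    #: exact Venn region (caller combination) -> number of keys found in
    #: exactly that combination of callers
    regions: dict[frozenset, int] = field(default_factory=dict, repr=False)

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    def tool_specific_pct(self) -> dict[str, float]:
        """Tool-specific calls as % of each tool's total, half-up 1 decimal."""
        out = {}
        for c in self.callers:
            total = self.per_tool_total[c]
            out[c] = round_half_up(100.0 * len(self.tool_specific[c]) / total, 1) if total else float("nan")
        return out


def _support_map(callsets: Sequence[Callset]) -> dict[VariantKey, frozenset]:
    if len(callsets) < 2:
        raise ValueError("consensus requires at least two callsets")
    groups = {cs.group for cs in callsets}
    if len(groups) != 1:
        raise ValueError(f"callsets span multiple groups: {sorted(groups)}")
    callers = [cs.caller for cs in callsets]
    if len(set(callers)) != len(callers):
        raise ValueError(f"duplicate caller labels: {callers}")
    membership: dict[VariantKey, set] = {}
    for cs in callsets:
        for key in cs.records:
            membership.setdefault(key, set()).add(cs.caller)
    return {k: frozenset(v) for k, v in membership.items()}


def multicom(callsets: Sequence[Callset], min_support: int = 2) -> ConsensusResult:
    """Select SNPs reported by at least ``min_support`` callers.

    ``min_support=1`` yields the union of all callsets and
    ``min_support=len(callsets)`` their intersection.
    """
    membership = _support_map(callsets)
    n = len(callsets)
    if not 1 <= min_support <= n:
        raise ValueError(f"min_support must be in [1, {n}], got {min_support}")

    callers = tuple(cs.caller for cs in callsets)
    regions = Counter(membership.values())
    hist: dict[int, int] = {level: 0 for level in range(1, n + 1)}
    for combo, count in regions.items():
        hist[len(combo)] += count

    shared = frozenset(k for k, combo in membership.items() if len(combo) >= min_support)
    tool_specific = {
        c: frozenset(k for k, combo in membership.items() if combo == frozenset((c,)))
        for c in callers
    }
    pairwise = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset((callers[i], callers[j]))
            pairwise[pair] = sum(count for combo, count in regions.items() if pair <= combo)
    triple = sum(count for combo, count in regions.items() if len(combo) == n)

    return ConsensusResult(
        group=callsets[0].group,
        k=min_support,
        callers=callers,
        per_tool_total={cs.caller: len(cs) for cs in callsets},
        pairwise=pairwise,
        triple=triple,
        shared=shared,
        tool_specific=tool_specific,
        support_histogram=hist,
        regions=dict(regions),
    )


def support_histogram(callsets: Sequence[Callset]) -> dict[int, int]:
    """Number of distinct keys supported by exactly 1..n callers.

    Values sum to the size of the union of all callset keys.
    """
    membership = _support_map(callsets)
    hist = {level: 0 for level in range(1, len(callsets) + 1)}
    for combo in membership.values():
        hist[len(combo)] += 1
    return hist


def discovery_gain(result: ConsensusResult) -> dict[str, float | None]:
    """Relative gain of the consensus set over each tool's own total.

    ``gain = (|shared| - per_tool_total) / per_tool_total``; negative when a
    tool alone called more than the consensus retained. ``None`` flags a
    caller with zero calls (gain undefined).
    """
    gains: dict[str, float | None] = {}
    for caller, total in result.per_tool_total.items():
        gains[caller] = (len(result.shared) - total) / total if total else None
    return gains
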