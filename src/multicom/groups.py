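"""Partition the two groups' consensus SNP sets into specific and common calls.

A SNP is group-specific when it is in one group's consensus set and absent
from the other's — whether genuinely absent or merely sub-threshold there.
SNPs in both sets are "common" (in a cross-species alignment setting these
are largely generic reference-vs-subject differences rather than
within-cohort polymorphism).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet

from multicom._util import pct
from multicom.variants import VariantKey

__all__ = ["GroupPartition", "partition_groups"]


@dataclass(frozen=True)
class GroupPartition:
    """High-specific / low-specific / common SNP sets with percentages."""

    specific_high: frozenset[VariantKey]
    specific_low: frozenset[VariantKey]
    common: frozenset[VariantKey]

    @property
    def pct_specific_high(self) -> float | None:
        """High-specific share of the high group's consensus set, half-up 1dp."""
        denom = len(self.specific_high) + len(self.common)
        return pct(len(self.specific_high), denom) if denom else None

    @property
    def pct_specific_low(self) -> float | None:
        denom = len(self.specific_low) + len(self.common)
        return pct(len(self.specific_low), denom) if denom else None


def partition_groups(mc_high: AbstractSet[VariantKey], mc_low: AbstractSet[VariantKey]) -> GroupPartition:
    """Split two consensus key sets into specific and common subsets."""
    mc_high = frozenset(mc_high)
    mc_low = frozenset(mc_low)
    return GroupPartition(
        specific_high=mc_high - mc_low,
        specific_low=mc_low - mc_high,
        common=mc_high & mc_low,
    )
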