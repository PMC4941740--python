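"""Transition/transversion diagnostics and region-class composition.

A consensus set of true SNPs in exome targets is expected to show a high
ts/tv ratio (~2.6–3.5), while sets contaminated by caller-specific false
positives drift towards the 0.5 expected of random substitutions and are
enriched for intergenic placements. These diagnostics quantify both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from multicom._util import round_half_up
from multicom.genes import Annotation, annotate_variant
from multicom.variants import BASES, VariantKey

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

#: buckets used for region composition reporting; CDS and exon collapse
#: into "exonic"
REGION_CLASSES = ("exonic", "5UTR", "3UTR", "intronic", "intergenic")
_CLASS_BUCKET = {"CDS": "exonic", "exon": "exonic", "5UTR": "5UTR", "3UTR": "3UTR",
                 "intronic": "intronic", "intergenic": "intergenic"}

__all__ = ["TsTvReport", "RegionComposition", "TsTvComparison", "classify_substitution",
           "tstv_ratio", "compare_tstv", "region_composition", "REGION_CLASSES"]


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a base substitution as ``"transition"`` or ``"transversion"``.

    A<->G and C<->T (within-purine / within-pyrimidine changes) are
    transitions; the remaining eight ordered pairs are transversions.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid bases {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


@dataclass(frozen=True)
class TsTvReport:
    """Transition/transversion counts for one call class."""

    label: str
    group: str
    ts: int
    tv: int

    @property
    def n(self) -> int:
        return self.ts + self.tv

    @property
    def ratio(self) -> float | None:
        """ts/tv, or ``None`` when no transversions were observed."""
        return self.ts / self.tv if self.tv > 0 else None

    @property
    def ratio_2dp(self) -> float | None:
        return None if self.ratio is None else round_half_up(self.ratio, 2)


def tstv_ratio(keys: Iterable[VariantKey], label: str = "", group: str = "") -> TsTvReport:
    """Count transitions and transversions over a set of SNP keys."""
    ts = tv = 0
    for key in keys:
        if classify_substitution(key.ref, key.alt) == "transition":
            ts += 1
        else:
            tv += 1
    if ts + tv == 0:
        raise ValueError("ts/tv ratio is undefined for an empty variant set")
    return TsTvReport(label=label, group=group, ts=ts, tv=tv)


@dataclass(frozen=True)
class TsTvComparison:
    statistic: float
    pvalue: float
    mean_specific: float
    mean_shared: float
    method: str


def _ratios(reports: Sequence["TsTvReport | float"]) -> list[float]:
    out = []
    for r in reports:
        ratio = r.ratio if isinstance(r, TsTvReport) else float(r)
        if ratio is None:
            raise ValueError(f"undefined ts/tv ratio in comparison input: {r}")
        out.append(ratio)
    return out


def compare_tstv(specific_reports: Sequence["TsTvReport | float"],
                 shared_reports: Sequence["TsTvReport | float"],
                 method: str = "welch", alternative: str = "two-sided") -> TsTvComparison:
    """Two-sample location test on ts/tv ratios of specific vs shared calls.

    ``method`` is ``"welch"`` (unequal-variance t-test, default) or
    ``"mannwhitney"``. ``alternative="less"`` tests whether specific ratios
    are lower than shared ones.
    """
    specific = _ratios(specific_reports)
    shared = _ratios(shared_reports)
    if len(specific) < 2 or len(shared) < 2:
        raise ValueError("need at least two ratios on each side")
    if method == "welch":
        res = stats.ttest_ind(specific, shared, equal_var=False, alternative=alternative)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(specific, shared, alternative=alternative)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TsTvComparison(statistic=float(res.statistic), pvalue=float(res.pvalue),
                          mean_specific=float(sum(specific) / len(specific)),
                          mean_shared=float(sum(shared) / len(shared)), method=method)


@dataclass(frozen=True)
class RegionComposition:
    """Counts of SNPs per genomic region class."""

    label: str
    group: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def intergenic_fraction(self) -> float:
        return self.counts.get("intergenic", 0) / self.total if self.total else 0.0


def region_composition(keys: Iterable[VariantKey], annotation: Annotation,
                       label: str = "", group: str = "") -> RegionComposition:
    """Assign each key one region class and tally the composition."""
    counts = {cls: 0 for cls in REGION_CLASSES}
    for key in keys:
        cls, _ = annotate_variant(key, annotation)
        counts[_CLASS_BUCKET[cls]] += 1
    return RegionComposition(label=label, group=group, counts=counts)
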