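"""Interval-based gene and region annotation of SNPs.

Annotation is agnostic to its source: BED (0-based half-open) and GFF3
(1-based inclusive) are both converted to internal 0-based half-open
intervals. A SNP position is assigned a single region class by precedence
``CDS > 5UTR > 3UTR > exon > intronic (gene body outside exons) >
intergenic``; introns are inferred rather than read from the file, since
most annotation dialects do not list them. Strand is ignored.
"""

from __future__ import annotations

import bisect
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import unquote

from multicom.variants import VariantKey, normalize_chrom

logger = logging.getLogger(__name__)

FEATURES = ("CDS", "5UTR", "3UTR", "exon", "gene")
#: region-class precedence, highest first; "intronic"/"intergenic" are derived
CLASS_PRECEDENCE = ("CDS", "5UTR", "3UTR", "exon", "intronic")

_GFF_FEATURE_MAP = {
    "cds": "CDS",
    "five_prime_utr": "5UTR",
    "5utr": "5UTR",
    "three_prime_utr": "3UTR",
    "3utr": "3UTR",
    "exon": "exon",
    "gene": "gene",
    "mrna": "gene",
    "transcript": "gene",
}

__all__ = ["GeneInterval", "Annotation", "GeneSetPartition", "load_annotation",
           "annotate_variant", "candidate_genes", "partition_reference", "write_gff3"]


@dataclass(frozen=True, slots=True)
class GeneInterval:
    """A gene feature interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    feature: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end} ({self.gene_id})")
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}; expected one of {FEATURES}")

    def contains(self, pos1: int) -> bool:
        """Whether the 1-based position falls inside this interval."""
        return self.start < pos1 <= self.end


class Annotation:
    """Point-query index over gene intervals.

    Per chromosome, intervals are sorted by start; queries use a bisect
    bounded by the longest interval on that chromosome. Overlapping
    intervals are permitted.
    """

    def __init__(self, intervals: Iterable[GeneInterval]):
        self.intervals: list[GeneInterval] = list(intervals)
        self._by_chrom: dict[str, list[GeneInterval]] = {}
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self._starts[chrom] = [iv.start for iv in ivs]
            self._max_len[chrom] = max(iv.end - iv.start for iv in ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def query(self, chrom: str, pos1: int) -> list[GeneInterval]:
        """All intervals containing the 1-based position."""
        chrom = normalize_chrom(chrom)
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return []
        hi = bisect.bisect_left(self._starts[chrom], pos1)  # starts strictly left of pos (0-based start < pos1)
        lo = bisect.bisect_left(self._starts[chrom], pos1 - self._max_len[chrom])
        return [iv for iv in ivs[lo:hi] if iv.contains(pos1)]

    def gene_ids(self) -> frozenset[str]:
        return frozenset(iv.gene_id for iv in self.intervals)


def _parse_bed_line(fields: Sequence[str], path, line_no: int) -> GeneInterval:
    try:
        chrom = normalize_chrom(fields[0])
        start, end = int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}:{line_no}: malformed BED line: {exc}") from exc
    gene_id = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else f"{chrom}:{start}-{end}"
    feature = fields[6] if len(fields) > 6 and fields[6] else "gene"
    return GeneInterval(gene_id=gene_id, chrom=chrom, start=start, end=end, feature=feature)


def _gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = unquote(v.strip())
    return attrs


def _parse_gff3_line(fields: Sequence[str], path, line_no: int) -> GeneInterval | None:
    if len(fields) < 9:
        raise ValueError(f"{path}:{line_no}: GFF3 line has {len(fields)} columns, expected 9")
    feature = _GFF_FEATURE_MAP.get(fields[2].lower())
    if feature is None:
        logger.warning("%s:%d: skipping unknown feature type %r", path, line_no, fields[2])
        return None
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise ValueError(f"{path}:{line_no}: malformed GFF3 coordinates: {exc}") from exc
    attrs = _gff3_attributes(fields[8])
    gene_id = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID") or attrs.get("Name")
    if gene_id is None:
        raise ValueError(f"{path}:{line_no}: GFF3 record lacks gene_id/Parent/ID/Name attribute")
    return GeneInterval(gene_id=gene_id, chrom=normalize_chrom(fields[0]),
                        start=start1 - 1, end=end1, feature=feature)


def load_annotation(path: str | os.PathLike, fmt: str | None = None) -> Annotation:
    """Load gene intervals from BED or GFF3 (``fmt`` inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    fmt = fmt.lower()
    if fmt not in {"bed", "gff3"}:
        raise ValueError(f"unknown annotation format {fmt!r}")
    intervals: list[GeneInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (fmt == "bed" and line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                iv = _parse_bed_line(fields, path, line_no)
            else:
                iv = _parse_gff3_line(fields, path, line_no)
            if iv is not None:
                intervals.append(iv)
    return Annotation(intervals)


def write_gff3(intervals: Iterable[GeneInterval], path: str | os.PathLike, source: str = "multicom") -> None:
    """Write intervals as GFF3 (inverse of :func:`load_annotation`)."""
    reverse = {"CDS": "CDS", "5UTR": "five_prime_UTR", "3UTR": "three_prime_UTR",
               "exon": "exon", "gene": "gene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            fh.write(f"{iv.chrom}\t{source}\t{reverse[iv.feature]}\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                     f"ID={iv.gene_id}.{iv.feature}.{iv.start};gene_id={iv.gene_id}\n")


def annotate_variant(key: VariantKey, annotation: Annotation) -> tuple[str, frozenset[str]]:
    """Assign one region class and the gene ids of the winning class.

    Returns ``(region_class, gene_ids)`` with class one of CDS, 5UTR, 3UTR,
    exon, intronic or intergenic; intergenic yields an empty gene set.
    A hit inside a gene body with no overlapping exon-level feature counts
    as intronic.
    """
    hits = annotation.query(key.chrom, key.pos)
    if not hits:
        return "intergenic", frozenset()
    by_feature: dict[str, set[str]] = {}
    for iv in hits:
        by_feature.setdefault(iv.feature, set()).add(iv.gene_id)
    for cls in ("CDS", "5UTR", "3UTR", "exon"):
        if cls in by_feature:
            return cls, frozenset(by_feature[cls])
    return "intronic", frozenset(by_feature["gene"])


def candidate_genes(keys: Iterable[VariantKey], annotation: Annotation) -> dict[str, int]:
    """Genes hit by any non-intergenic SNP, with supporting SNP counts."""
    counts: Counter[str] = Counter()
    for key in keys:
        _, gene_ids = annotate_variant(key, annotation)
        counts.update(gene_ids)
    return dict(counts)


@dataclass
class GeneSetPartition:
    """Partition of a reference gene list against two groups' candidates."""

    reference_name: str
    common: frozenset[str]
    low_only: frozenset[str]
    high_only: frozenset[str]
    absent: frozenset[str]

    @property
    def total_overlap(self) -> int:
        return len(self.common) + len(self.low_only) + len(self.high_only)

    def __post_init__(self) -> None:
        parts = (self.common, self.low_only, self.high_only, self.absent)
        total = sum(len(p) for p in parts)
        union = frozenset().union(*parts)
        if total != len(union):
            raise AssertionError("partition sets overlap")


def partition_reference(genes_high: Iterable[str], genes_low: Iterable[str],
                        reference: Iterable[str], reference_name: str = "reference",
                        case_insensitive: bool = False) -> GeneSetPartition:
    """Split a reference gene list by which group's candidates recover it."""
    fold = (lambda g: g.casefold()) if case_insensitive else (lambda g: g)
    ref_list = [fold(g) for g in reference]
    ref = frozenset(ref_list)
    if len(ref_list) != len(ref):
        logger.warning("reference %s contains %d duplicate ids; deduplicated",
                       reference_name, len(ref_list) - len(ref))
    high = frozenset(map(fold, genes_high))
    low = frozenset(map(fold, genes_low))
    common = ref & high & low
    high_only = (ref & high) - low
    low_only = (ref & low) - high
    absent = ref - high - low
    return GeneSetPartition(reference_name=reference_name, common=common,
                            low_only=low_only, high_only=high_only, absent=absent)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))
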