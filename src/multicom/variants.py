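"""SNP callset model and VCF input/output.

Variant identity is the biallelic tuple ``(chrom, pos, ref, alt)`` after
multi-allelic splitting. Chromosome names are normalised by stripping a
leading ``chr`` prefix so that callsets produced against mixed reference
dialects can be intersected. Only single-base substitutions are kept;
indels, MNPs and symbolic alleles are dropped (and counted).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

__all__ = [
    "VariantKey",
    "VariantRecord",
    "Callset",
    "VcfParseError",
    "read_vcf",
    "filter_callset",
    "write_vcf",
    "normalize_chrom",
]


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr``/``CHR`` prefix from a chromosome name."""
    if name[:3].lower() == "chr" and len(name) > 3:
        return name[3:]
    return name


@dataclass(frozen=True, order=True, slots=True)
class VariantKey:
    """Canonical identity of a biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single upper-case bases, got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A SNP call with its quality and depth evidence.

    ``qual`` / ``depth`` are ``None`` when the caller did not report them;
    missing values always fail the corresponding filter criterion.

    Quality is carried at 3-decimal precision: VCF stores QUAL as a 32-bit
    float, and quantizing here keeps ``read(write(cs)) == cs`` exact.
    """

    key: VariantKey
    qual: float | None
    depth: int | None

    def __post_init__(self) -> None:
        if self.qual is not None:
            object.__setattr__(self, "qual", round(float(self.qual), 3))
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be non-negative")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass
class Callset:
    """One caller's SNP set for one sample group.

    Records are keyed by :class:`VariantKey`; a callset never contains two
    records with the same key. ``meta`` carries bookkeeping (dropped-allele
    counts, filter reports) and does not participate in equality.
    """

    caller: str
    group: str
    records: dict[VariantKey, VariantRecord] = field(default_factory=dict)
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.caller or not self.group:
            raise ValueError("caller and group labels must be non-empty")

    @classmethod
    def from_records(cls, caller: str, group: str, records: Iterable[VariantRecord], **meta) -> "Callset":
        mapping: dict[VariantKey, VariantRecord] = {}
        for rec in records:
            if rec.key in mapping:
                raise ValueError(f"duplicate variant key {rec.key}")
            mapping[rec.key] = rec
        return cls(caller=caller, group=group, records=mapping, meta=dict(meta))

    @property
    def keys(self) -> frozenset[VariantKey]:
        return frozenset(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.records


def _record_depth(variant) -> int | None:
    """INFO/DP, falling back to the sum of per-sample FORMAT/DP values."""
    dp = variant.INFO.get("DP")
    if dp is not None:
        return int(dp)
    try:
        sample_dp = variant.format("DP")
    except KeyError:
        sample_dp = None
    if sample_dp is not None:
        total = int(sample_dp[sample_dp >= 0].sum())
        if (sample_dp >= 0).any():
            return total
    return None


def read_vcf(path: str | os.PathLike, caller: str = "unknown", group: str = "unknown",
             sample_pooling: bool = True) -> Callset:
    """Read a VCF (plain or bgzipped) into a SNP-only :class:`Callset`.

    Multi-allelic records are split into one record per alternate allele;
    non-SNP alleles are dropped and counted in ``meta["n_dropped_non_snp"]``.
    ``sample_pooling`` documents that a multi-sample VCF is treated as one
    pooled callset (per-sample VCFs of a group should be unioned upstream).

    Raises ``FileNotFoundError`` for a missing file and :class:`VcfParseError`
    (naming the approximate line) for malformed content.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such VCF file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError/Exception on bad headers
        raise VcfParseError(f"{path}: not a parseable VCF: {exc}") from exc

    if not sample_pooling and len(vcf.samples) > 1:
        logger.warning("%s: %d samples treated as one pooled group", path, len(vcf.samples))

    records: dict[VariantKey, VariantRecord] = {}
    n_dropped = 0
    n_duplicate = 0
    line_no = 0
    try:
        for variant in vcf:
            line_no += 1
            chrom = normalize_chrom(variant.CHROM)
            ref = variant.REF.upper()
            depth = _record_depth(variant)
            qual = variant.QUAL  # None when '.'
            for alt in variant.ALT:
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
                    n_dropped += 1
                    continue
                key = VariantKey(chrom, variant.POS, ref, alt)
                if key in records:
                    n_duplicate += 1
                    continue
                records[key] = VariantRecord(key=key, qual=qual, depth=depth)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF record near data line {line_no + 1}: {exc}") from exc
    finally:
        vcf.close()

    if n_dropped:
        logger.info("%s: dropped %d non-SNP alternate alleles", path, n_dropped)
    return Callset(caller=caller, group=group, records=records,
                   meta={"n_dropped_non_snp": n_dropped, "n_duplicate_keys": n_duplicate,
                         "source": str(path)})


def filter_callset(cs: Callset, min_depth: int = 5, min_qual: float = 30.0) -> Callset:
    """Keep records with ``depth >= min_depth`` and ``qual >= min_qual``.

    Thresholds are inclusive. Missing depth or quality fails the respective
    criterion. The input callset is not modified; per-criterion removal
    counts are reported in the result's ``meta["filter"]``.
    """
    if min_depth < 0 or min_qual < 0:
        raise ValueError("thresholds must be non-negative")
    kept: dict[VariantKey, VariantRecord] = {}
    n_depth = n_qual = 0
    for rec in cs:
        depth_ok = rec.depth is not None and rec.depth >= min_depth
        qual_ok = rec.qual is not None and rec.qual >= min_qual
        if not depth_ok:
            n_depth += 1
        if not qual_ok:
            n_qual += 1
        if depth_ok and qual_ok:
            kept[rec.key] = rec
    report = {"min_depth": min_depth, "min_qual": min_qual,
              "n_input": len(cs), "n_kept": len(kept),
              "n_failed_depth": n_depth, "n_failed_qual": n_qual}
    return Callset(caller=cs.caller, group=cs.group, records=kept,
                   meta={**cs.meta, "filter": report})


def write_vcf(cs: Callset, path: str | os.PathLike) -> None:
    """Write a minimal sites-only VCF v4.2 with DP in INFO.

    Records are sorted by ``(chrom, pos, alt)``; ``read_vcf(write_vcf(cs))``
    reproduces the callset's (key, qual, depth) triples exactly.
    """
    path = Path(path)
    chroms = sorted({rec.key.chrom for rec in cs})
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at site">',
             f"##multicom_caller={cs.caller}",
             f"##multicom_group={cs.group}"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(cs, key=lambda r: (r.key.chrom, r.key.pos, r.key.alt)):
        qual = "." if rec.qual is None else f"{rec.qual:.10g}"
        info = "." if rec.depth is None else f"DP={rec.depth}"
        k = rec.key
        lines.append(f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t{qual}\tPASS\t{info}")
    path.write_text("\n".join(lines) + "\n")


def union_callsets(callsets: Iterable[Callset], caller: str, group: str) -> Callset:
    """Union per-sample callsets of one caller into a pooled group callset.

    When the same key appears in several inputs the record with the highest
    quality (then depth) is retained.
    """
    best: dict[VariantKey, VariantRecord] = {}
    for cs in callsets:
        for rec in cs:
            cur = best.get(rec.key)
            if cur is None or ((rec.qual or 0, rec.depth or 0) > (cur.qual or 0, cur.depth or 0)):
                best[rec.key] = rec
    logger.info("pooled %s/%s callset from per-sample union", caller, group)
    return Callset(caller=caller, group=group, records=best, meta={"pooled_union": True})
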