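"""Synthetic multi-caller, two-group callset generator.

The simulator produces everything the pipeline consumes — per-caller VCFs
for two groups, a gene annotation, gene lists and a DEG table — with the
error structure the consensus diagnostics assume: true variants share a
high transition/transversion mix, while per-caller false positives are
independent across callers, carry a lower ts/tv mix and land in intergenic
sequence at an elevated rate.

All randomness flows from ``SimConfig.seed``: every consumer derives its
own stream via ``numpy.random.SeedSequence(seed, spawn_key=(crc32(name),))``
so that, e.g., one caller's callset does not depend on whether another
caller was simulated first.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping

import numpy as np
import pandas as pd

from multicom.genes import Annotation, GeneInterval, candidate_genes, write_gff3, write_gene_list
from multicom.variants import Callset, VariantKey, VariantRecord, write_vcf

BASES = ("A", "C", "G", "T")
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION_PARTNERS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

DEFAULT_CALLERS = ("samtools", "freebayes", "varscan")

__all__ = ["SimConfig", "SimTruth", "simulate_truth", "simulate_caller",
           "simulate_group", "simulate_deg", "rng_for"]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named independent random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset."""

    genome: tuple[tuple[str, int], ...] = (("1", 2_000_000), ("2", 2_000_000))
    n_true_high: int = 1500
    n_true_low: int = 1500
    n_common_true: int = 7000
    tstv_true: float = 2.6
    tstv_fp: float = 1.8
    caller_sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.95 for c in DEFAULT_CALLERS})
    #: expected false-positive count per caller; None means 5% of the
    #: group's truth size
    caller_fp_rate: Mapping[str, float] | None = None
    true_intergenic_fraction: float = 0.3
    fp_intergenic_multiplier: float = 2.0
    #: fraction of detected calls written with sub-threshold QUAL or DP
    subthreshold_fraction: float = 0.05
    #: fraction of each caller's FPs drawn from a pool shared by all
    #: callers; breaks FP independence (0 = fully independent errors)
    fp_shared_fraction: float = 0.0
    n_genes: int = 300
    exons_per_gene: int = 4
    gene_length: int = 5_000
    exon_length: int = 400
    n_deg: int = 400
    n_deg_background: int = 400
    deg_candidate_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_true_high", "n_true_low", "n_common_true", "n_genes",
                     "exons_per_gene", "n_deg", "n_deg_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tstv_true <= 0 or self.tstv_fp <= 0:
            raise ValueError("ts/tv targets must be positive")
        for name in ("true_intergenic_fraction", "subthreshold_fraction",
                     "fp_shared_fraction", "deg_candidate_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for caller, s in self.caller_sensitivity.items():
            if not 0 <= s <= 1:
                raise ValueError(f"sensitivity of {caller} must lie in [0, 1]")

    @property
    def n_truth(self) -> int:
        return self.n_true_high + self.n_true_low + self.n_common_true

    def fp_rate(self, caller: str, truth_size: int) -> float:
        if self.caller_fp_rate is not None:
            if caller not in self.caller_fp_rate:
                raise KeyError(f"no FP rate configured for caller {caller!r}")
            return float(self.caller_fp_rate[caller])
        return 0.05 * truth_size


def _build_annotation(cfg: SimConfig) -> list[GeneInterval]:
    """Lay genes at regular spacing; exons evenly spread inside each body."""
    spacing = 2 * cfg.gene_length
    capacity = sum(length // spacing for _, length in cfg.genome)
    if cfg.n_genes > capacity:
        raise ValueError(f"genome too small for {cfg.n_genes} genes (capacity {capacity})")
    intervals: list[GeneInterval] = []
    placed = 0
    per_chrom = {}
    for chrom, length in cfg.genome:
        per_chrom[chrom] = length // spacing
    # round-robin across chromosomes so genes spread evenly
    slots = []
    idx = {chrom: 0 for chrom, _ in cfg.genome}
    while placed < cfg.n_genes:
        progressed = False
        for chrom, _ in cfg.genome:
            if placed >= cfg.n_genes:
                break
            if idx[chrom] < per_chrom[chrom]:
                slots.append((chrom, idx[chrom]))
                idx[chrom] += 1
                placed += 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by capacity check
            raise ValueError("gene placement failed")
    gap = (cfg.gene_length - cfg.exons_per_gene * cfg.exon_length)
    if gap < 0:
        raise ValueError("exons do not fit inside gene body")
    step = cfg.gene_length // cfg.exons_per_gene
    for i, (chrom, slot) in enumerate(sorted(slots)):
        start = slot * 2 * cfg.gene_length + cfg.gene_length // 2
        gene_id = f"GENE{i + 1:05d}"
        intervals.append(GeneInterval(gene_id, chrom, start, start + cfg.gene_length, "gene"))
        for e in range(cfg.exons_per_gene):
            e_start = start + e * step
            intervals.append(GeneInterval(gene_id, chrom, e_start, e_start + cfg.exon_length, "exon"))
    return intervals


def _draw_alt(ref: str, ts_prob: float, rng: np.random.Generator) -> str:
    if rng.random() < ts_prob:
        return TRANSITION_PARTNER[ref]
    return TRANSVERSION_PARTNERS[ref][rng.integers(2)]


def _draw_positions(n: int, intergenic_fraction: float, cfg: SimConfig,
                    annotation: Annotation, rng: np.random.Generator,
                    occupied: set[tuple[str, int]]) -> list[tuple[str, int]]:
    """Unique (chrom, pos) sites, genic vs intergenic per the given fraction."""
    chroms = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    chrom_p = lengths / lengths.sum()
    genes = [iv for iv in annotation.intervals if iv.feature == "gene"]
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("genome too small for requested variant count")
        if genes and rng.random() >= intergenic_fraction:
            g = genes[rng.integers(len(genes))]
            site = (g.chrom, int(g.start + 1 + rng.integers(g.end - g.start)))
        else:
            # rejection-sample a position outside every gene body; retrying
            # inside this branch keeps the genic/intergenic mix unbiased
            while True:
                ci = rng.choice(len(chroms), p=chrom_p)
                site = (chroms[ci], int(rng.integers(cfg.genome[ci][1]) + 1))
                if not annotation.query(*site):
                    break
                attempts += 1
                if attempts > 200 * n + 1000:
                    raise ValueError("genome too small for requested variant count")
        if site in occupied:
            continue
        occupied.add(site)
        out.append(site)
    return out


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    annotation: Annotation
    truth_high: frozenset[VariantKey]
    truth_low: frozenset[VariantKey]
    truth_common: frozenset[VariantKey]

    def truth_for_group(self, group: str) -> frozenset[VariantKey]:
        if group == "high":
            return self.truth_high | self.truth_common
        if group == "low":
            return self.truth_low | self.truth_common
        raise ValueError(f"unknown group {group!r}")

    @property
    def all_truth(self) -> frozenset[VariantKey]:
        return self.truth_high | self.truth_low | self.truth_common

    def gene_universe(self) -> frozenset[str]:
        return self.annotation.gene_ids()

    def candidate_gene_sets(self) -> dict[str, frozenset[str]]:
        """Genes hit by high-specific / low-specific / common truth variants."""
        return {name: frozenset(candidate_genes(keys, self.annotation))
                for name, keys in (("high", self.truth_high), ("low", self.truth_low),
                                   ("common", self.truth_common))}


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Generate annotation and disjoint high/low/common truth variant sets."""
    rng = rng_for(cfg.seed, "truth")
    annotation = Annotation(_build_annotation(cfg))
    occupied: set[tuple[str, int]] = set()
    sites = _draw_positions(cfg.n_truth, cfg.true_intergenic_fraction, cfg, annotation, rng, occupied)
    ts_prob = cfg.tstv_true / (1.0 + cfg.tstv_true)
    keys = []
    for chrom, pos in sites:
        ref = BASES[rng.integers(4)]
        keys.append(VariantKey(chrom, pos, ref, _draw_alt(ref, ts_prob, rng)))
    rng.shuffle(keys)
    high = frozenset(keys[:cfg.n_true_high])
    low = frozenset(keys[cfg.n_true_high:cfg.n_true_high + cfg.n_true_low])
    common = frozenset(keys[cfg.n_true_high + cfg.n_true_low:])
    return SimTruth(config=cfg, annotation=annotation, truth_high=high,
                    truth_low=low, truth_common=common)


def _sample_evidence(n: int, rng: np.random.Generator, cfg: SimConfig,
                     min_depth: int = 5, min_qual: float = 30.0):
    """(qual, depth) arrays; a configurable fraction falls below threshold."""
    qual = rng.uniform(min_qual, 100.0, size=n)
    depth = rng.integers(min_depth, 60, size=n)
    fail = rng.random(n) < cfg.subthreshold_fraction
    which = rng.integers(2, size=n)
    qual[fail & (which == 0)] = rng.uniform(0.0, min_qual, size=int((fail & (which == 0)).sum()))
    depth[fail & (which == 1)] = rng.integers(0, min_depth, size=int((fail & (which == 1)).sum()))
    return qual, depth


def _make_fp_keys(n: int, truth: SimTruth, rng: np.random.Generator,
                  occupied: set[tuple[str, int]]) -> list[VariantKey]:
    cfg = truth.config
    fp_intergenic = min(1.0, cfg.true_intergenic_fraction * cfg.fp_intergenic_multiplier)
    sites = _draw_positions(n, fp_intergenic, cfg, truth.annotation, rng, occupied)
    ts_prob = cfg.tstv_fp / (1.0 + cfg.tstv_fp)
    keys = []
    for chrom, pos in sites:
        ref = BASES[rng.integers(4)]
        keys.append(VariantKey(chrom, pos, ref, _draw_alt(ref, ts_prob, rng)))
    return keys


def simulate_caller(truth: SimTruth, caller: str, group: str,
                    shared_fp_pool: list[VariantKey] | None = None) -> Callset:
    """Simulate one caller's callset for one group.

    Each true variant is detected independently with the caller's
    sensitivity; false positives are Poisson-distributed with the
    configured expectation and placed with the intergenic bias. QUAL/DP
    are drawn above the default thresholds except for the configured
    sub-threshold fraction (exercising the filter stage).
    """
    cfg = truth.config
    if caller not in cfg.caller_sensitivity:
        raise KeyError(f"unknown caller label {caller!r}; configured: {sorted(cfg.caller_sensitivity)}")
    rng = rng_for(cfg.seed, f"caller:{caller}:{group}")
    group_truth = sorted(truth.truth_for_group(group))

    detected = [k for k in group_truth if rng.random() < cfg.caller_sensitivity[caller]]

    n_fp = int(rng.poisson(cfg.fp_rate(caller, len(group_truth))))
    n_shared = 0
    fp_keys: list[VariantKey] = []
    if shared_fp_pool and cfg.fp_shared_fraction > 0:
        n_shared = min(len(shared_fp_pool), int(round(n_fp * cfg.fp_shared_fraction)))
        fp_keys.extend(shared_fp_pool[:n_shared])
    occupied = {(k.chrom, k.pos) for k in truth.all_truth}
    occupied.update((k.chrom, k.pos) for k in fp_keys)
    fp_keys.extend(_make_fp_keys(n_fp - n_shared, truth, rng, occupied))

    keys = detected + fp_keys
    qual, depth = _sample_evidence(len(keys), rng, cfg)
    records = (VariantRecord(key=k, qual=float(q), depth=int(d))
               for k, q, d in zip(keys, qual, depth))
    return Callset.from_records(caller, group, records,
                                n_true_detected=len(detected), n_fp=len(fp_keys))


def simulate_group(truth: SimTruth, group: str,
                   callers: Iterable[str] | None = None) -> dict[str, Callset]:
    """Simulate all callers for one group, honouring the shared-FP knob."""
    cfg = truth.config
    callers = tuple(callers) if callers is not None else tuple(sorted(cfg.caller_sensitivity))
    pool: list[VariantKey] | None = None
    if cfg.fp_shared_fraction > 0:
        rng = rng_for(cfg.seed, f"shared-fp:{group}")
        group_truth = truth.truth_for_group(group)
        pool_size = int(max(cfg.fp_rate(c, len(group_truth)) for c in callers))
        occupied = {(k.chrom, k.pos) for k in truth.all_truth}
        pool = _make_fp_keys(pool_size, truth, rng, occupied)
    return {c: simulate_caller(truth, c, group, shared_fp_pool=pool) for c in callers}


def simulate_deg(universe: AbstractSet[str], candidates: AbstractSet[str],
                 cfg: SimConfig) -> pd.DataFrame:
    """DEG table with a controllable fraction of DEG drawn from candidates.

    Rows below p=0.01 are the simulated DEG (balanced up/down logFC signs);
    background rows carry non-significant p-values.
    """
    rng = rng_for(cfg.seed, "deg")
    universe = sorted(universe)
    candidates = sorted(set(candidates) & set(universe))
    background = sorted(set(universe) - set(candidates))
    if cfg.n_deg + cfg.n_deg_background > len(universe):
        raise ValueError("requested DEG + background exceeds the gene universe")
    n_from_cand = min(len(candidates), int(round(cfg.n_deg * cfg.deg_candidate_fraction)))
    deg_genes = list(rng.choice(candidates, size=n_from_cand, replace=False)) if n_from_cand else []
    remaining = sorted(set(universe) - set(deg_genes))
    deg_genes += list(rng.choice(remaining, size=cfg.n_deg - n_from_cand, replace=False))
    non_deg_pool = sorted(set(universe) - set(deg_genes))
    bg_genes = list(rng.choice(non_deg_pool, size=cfg.n_deg_background, replace=False))

    n = len(deg_genes)
    signs = np.where(np.arange(n) < n // 2, -1.0, 1.0)
    rng.shuffle(signs)
    rows = [{"gene_id": g,
             "logfc": float(s * rng.uniform(0.5, 4.0)),
             "pvalue": float(rng.uniform(1e-8, 0.0095))}
            for g, s in zip(deg_genes, signs)]
    rows += [{"gene_id": g,
              "logfc": float(rng.choice([-1.0, 1.0]) * rng.uniform(0.0, 0.5)) or 0.1,
              "pvalue": float(rng.uniform(0.02, 1.0))}
             for g in bg_genes]
    df = pd.DataFrame(rows, columns=["gene_id", "logfc", "pvalue"])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def write_simulation(truth: SimTruth, outdir: str | os.PathLike,
                     callers: Iterable[str] | None = None) -> dict[str, str]:
    """Write VCFs, GFF3 annotation, gene lists, DEG TSV and a truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    write_gff3(truth.annotation.intervals, outdir / "annotation.gff3")
    paths["annotation"] = str(outdir / "annotation.gff3")

    for group in ("high", "low"):
        for caller, cs in simulate_group(truth, group, callers).items():
            p = outdir / f"{group}.{caller}.vcf"
            write_vcf(cs, p)
            paths[f"vcf:{group}:{caller}"] = str(p)

    gene_sets = truth.candidate_gene_sets()
    for name, genes in gene_sets.items():
        p = outdir / f"genes_{name}_truth.txt"
        write_gene_list(genes, p)
        paths[f"genes:{name}"] = str(p)
    write_gene_list(truth.gene_universe(), outdir / "universe.txt")
    paths["universe"] = str(outdir / "universe.txt")

    deg = simulate_deg(truth.gene_universe(),
                       gene_sets["high"] | gene_sets["low"] | gene_sets["common"],
                       truth.config)
    deg.to_csv(outdir / "deg.tsv", sep="\t", index=False)
    paths["deg"] = str(outdir / "deg.tsv")

    manifest = pd.DataFrame(
        [{"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "subset": subset}
         for subset, keys in (("high_specific", truth.truth_high),
                              ("low_specific", truth.truth_low),
                              ("common", truth.truth_common))
         for k in sorted(keys)])
    manifest.to_csv(outdir / "truth_manifest.tsv", sep="\t", index=False)
    paths["truth_manifest"] = str(outdir / "truth_manifest.tsv")
    return paths
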