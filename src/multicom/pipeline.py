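"""End-to-end orchestration: filter -> consensus -> QC -> group partition ->
gene annotation -> QTL partition -> enrichment -> DEG overlap -> summaries.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same configuration reproduces the JSON summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from multicom import consensus as consensus_mod
from multicom import degs as degs_mod
from multicom import enrichment as enrichment_mod
from multicom import genes as genes_mod
from multicom import groups as groups_mod
from multicom import runstats as runstats_mod
from multicom import tstv as tstv_mod
from multicom import variants as variants_mod

logger = logging.getLogger(__name__)

GROUPS = ("high", "low")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run."""

    #: group -> caller -> VCF path
    vcfs: Mapping[str, Mapping[str, str]]
    annotation: str
    outdir: str
    min_depth: int = 5
    min_qual: float = 30.0
    min_support: int = 2
    enrichment_alpha: float = 0.01
    deg_alpha: float = 0.01
    #: optional reference gene lists, name -> path
    references: Mapping[str, str] = field(default_factory=dict)
    deg_table: str | None = None
    universe: str | None = None
    gmt: str | None = None
    run_metrics: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; write artifacts and a JSON summary.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict(), "stages": {}}

    filtered = _run_filter(cfg, summary)
    results = _run_consensus(cfg, summary, filtered, outdir)
    annotation = _load_annotation(cfg)
    _run_tstv(cfg, summary, results, annotation)
    partition = _run_groupdiff(cfg, summary, results, outdir)
    gene_sets = _run_genes(cfg, summary, partition, annotation, outdir)
    _run_qtl(cfg, summary, gene_sets)
    _run_enrich(cfg, summary, gene_sets, annotation)
    _run_deg(cfg, summary, gene_sets, annotation)
    _run_metrics(cfg, summary)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


@_stage("filter")
def _run_filter(cfg: PipelineConfig, summary: dict) -> dict[str, dict[str, variants_mod.Callset]]:
    filtered: dict[str, dict[str, variants_mod.Callset]] = {}
    report = {}
    for group in GROUPS:
        if group not in cfg.vcfs:
            raise ValueError(f"no VCFs configured for group {group!r}")
        filtered[group] = {}
        for caller, path in cfg.vcfs[group].items():
            cs = variants_mod.read_vcf(path, caller=caller, group=group)
            fcs = variants_mod.filter_callset(cs, cfg.min_depth, cfg.min_qual)
            filtered[group][caller] = fcs
            report[f"{group}:{caller}"] = fcs.meta["filter"]
    summary["stages"]["filter"] = report
    return filtered


@_stage("consensus")
def _run_consensus(cfg, summary, filtered, outdir) -> dict[str, consensus_mod.ConsensusResult]:
    results = {}
    report = {}
    for group, callsets in filtered.items():
        res = consensus_mod.multicom(list(callsets.values()), cfg.min_support)
        results[group] = res
        gains = consensus_mod.discovery_gain(res)
        report[group] = {
            "per_tool_total": res.per_tool_total,
            "n_shared": res.n_shared,
            "support_histogram": {str(k): v for k, v in res.support_histogram.items()},
            "tool_specific": {c: len(s) for c, s in res.tool_specific.items()},
            "tool_specific_pct": res.tool_specific_pct(),
            "discovery_gain": gains,
        }
        shared_cs = variants_mod.Callset.from_records(
            "multicom", group,
            (callsets[next(iter(callsets))].records.get(k) or variants_mod.VariantRecord(k, None, None)
             for k in sorted(res.shared)))
        variants_mod.write_vcf(shared_cs, outdir / f"{group}.shared.vcf")
    summary["stages"]["consensus"] = report
    return results


@_stage("annotation")
def _load_annotation(cfg) -> genes_mod.Annotation:
    return genes_mod.load_annotation(cfg.annotation)


@_stage("tstv")
def _run_tstv(cfg, summary, results, annotation) -> None:
    report = {}
    specific_reports, shared_reports = [], []
    for group, res in results.items():
        shared_rep = tstv_mod.tstv_ratio(res.shared, label="shared", group=group)
        shared_reports.append(shared_rep)
        comp = tstv_mod.region_composition(res.shared, annotation, label="shared", group=group)
        report[f"{group}:shared"] = {"ts": shared_rep.ts, "tv": shared_rep.tv,
                                     "ratio": shared_rep.ratio_2dp,
                                     "intergenic_fraction": comp.intergenic_fraction}
        for caller, keys in res.tool_specific.items():
            if not keys:
                continue
            rep = tstv_mod.tstv_ratio(keys, label=f"{caller}-specific", group=group)
            specific_reports.append(rep)
            comp = tstv_mod.region_composition(keys, annotation, label=rep.label, group=group)
            report[f"{group}:{caller}-specific"] = {"ts": rep.ts, "tv": rep.tv,
                                                    "ratio": rep.ratio_2dp,
                                                    "intergenic_fraction": comp.intergenic_fraction}
    if len(specific_reports) >= 2 and len(shared_reports) >= 2:
        cmp = tstv_mod.compare_tstv(specific_reports, shared_reports)
        report["comparison"] = {"statistic": cmp.statistic, "pvalue": cmp.pvalue,
                                "mean_specific": cmp.mean_specific, "mean_shared": cmp.mean_shared,
                                "method": cmp.method}
    summary["stages"]["tstv"] = report


@_stage("groupdiff")
def _run_groupdiff(cfg, summary, results, outdir) -> groups_mod.GroupPartition:
    part = groups_mod.partition_groups(results["high"].shared, results["low"].shared)
    summary["stages"]["groupdiff"] = {
        "n_specific_high": len(part.specific_high),
        "n_specific_low": len(part.specific_low),
        "n_common": len(part.common),
        "pct_specific_high": part.pct_specific_high,
        "pct_specific_low": part.pct_specific_low,
    }
    for name, keys in (("high_specific", part.specific_high),
                       ("low_specific", part.specific_low), ("common", part.common)):
        cs = variants_mod.Callset.from_records(
            "multicom", name, (variants_mod.VariantRecord(k, None, None) for k in sorted(keys)))
        variants_mod.write_vcf(cs, outdir / f"{name}.vcf")
    return part


@_stage("genes")
def _run_genes(cfg, summary, partition, annotation, outdir) -> dict[str, frozenset[str]]:
    gene_sets = {}
    report = {}
    for name, keys in (("high", partition.specific_high), ("low", partition.specific_low),
                       ("common", partition.common)):
        counts = genes_mod.candidate_genes(keys, annotation)
        gene_sets[name] = frozenset(counts)
        genes_mod.write_gene_list(counts, outdir / f"genes_{name}.txt")
        report[name] = {"n_genes": len(counts), "n_snps": len(keys)}
    # candidate categories must be disjoint for the DEG stage: resolve joint
    # hits by specificity precedence (a gene hit by both groups' specific
    # SNPs belongs to the common pool)
    both = gene_sets["high"] & gene_sets["low"]
    gene_sets["common"] = gene_sets["common"] | both
    gene_sets["high"] -= gene_sets["common"]
    gene_sets["low"] -= gene_sets["common"]
    report["disjoint"] = {k: len(v) for k, v in gene_sets.items()}
    summary["stages"]["genes"] = report
    return gene_sets


@_stage("qtl-partition")
def _run_qtl(cfg, summary, gene_sets) -> None:
    report = {}
    for name, path in cfg.references.items():
        ref = genes_mod.read_gene_list(path)
        part = genes_mod.partition_reference(gene_sets["high"] | gene_sets["common"],
                                             gene_sets["low"] | gene_sets["common"],
                                             ref, reference_name=name)
        report[name] = {"reference_size": len(set(ref)), "common": len(part.common),
                        "low_only": len(part.low_only), "high_only": len(part.high_only),
                        "absent": len(part.absent), "total_overlap": part.total_overlap}
    summary["stages"]["qtl_partition"] = report


@_stage("enrich")
def _run_enrich(cfg, summary, gene_sets, annotation) -> None:
    if cfg.gmt is None:
        summary["stages"]["enrich"] = None
        return
    terms = enrichment_mod.read_gmt(cfg.gmt)
    universe = (frozenset(genes_mod.read_gene_list(cfg.universe)) if cfg.universe
                else annotation.gene_ids())
    report = {}
    for name in ("high", "low"):
        results = enrichment_mod.enrich(gene_sets[name], terms, universe, cfg.enrichment_alpha)
        report[name] = [{"term": r.term, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                         "p": r.p, "p_adj": r.p_adj, "significant": r.significant}
                        for r in results]
    summary["stages"]["enrich"] = report


@_stage("deg-overlap")
def _run_deg(cfg, summary, gene_sets, annotation) -> None:
    if cfg.deg_table is None:
        summary["stages"]["deg_overlap"] = None
        return
    degs = degs_mod.load_deg(cfg.deg_table, cfg.deg_alpha)
    universe = (frozenset(genes_mod.read_gene_list(cfg.universe)) if cfg.universe
                else annotation.gene_ids())
    report = degs_mod.overlap_deg(degs, gene_sets["low"], gene_sets["high"],
                                  gene_sets["common"], universe)
    summary["stages"]["deg_overlap"] = {
        "n_deg": report.n_deg, "n_up": report.n_up, "n_down": report.n_down,
        "total_overlap": report.total_overlap, "overlap_fraction": report.overlap_fraction,
        "categories": [{"category": c.category, "n": c.n, "n_up": c.n_up,
                        "n_down": c.n_down, "pvalue": c.pvalue} for c in report.categories],
    }


@_stage("summarize")
def _run_metrics(cfg, summary) -> None:
    if cfg.run_metrics is None:
        summary["stages"]["summarize"] = None
        return
    rows = runstats_mod.read_run_metrics(cfg.run_metrics)
    summary["stages"]["summarize"] = dataclasses.asdict(runstats_mod.summarize_runs(rows))
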