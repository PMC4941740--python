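# multicom

Reproducibility-consensus SNP selection across variant callers, with the
downstream candidate-discovery chain: transition/transversion QC,
group-specific variant extraction, interval-based gene annotation,
reference (QTL) gene-list partitioning, hypergeometric gene-set
enrichment with Benjamini–Hochberg control, differential-expression
overlap accounting, and sequencing run-metric summaries. A seeded
simulator generates complete multi-caller, two-group datasets so every
stage is testable without external data.

## The consensus idea

Different variant callers disagree on a non-trivial fraction of SNP
calls, and the calls unique to a single tool behave like false
positives: their ts/tv ratio drifts down towards the ~0.5 expected of
random substitutions and they land in intergenic sequence at roughly
twice the rate of reproducible calls. Keeping only SNPs reported by at
least *k* of *n* callers (default 2 of 3) removes most of this noise
while the union over pairs *increases* the discovery rate relative to
any single caller.

## Library layout

| module | purpose |
| --- | --- |
| `multicom.variants` | VCF read/filter/write; `VariantKey` identity model (biallelic, multi-allelic records split, `chr` prefix stripped) |
| `multicom.consensus` | `multicom()` k-of-n consensus, Venn decomposition, `support_histogram`, `discovery_gain` |
| `multicom.tstv` | substitution classification, ts/tv reports, specific-vs-shared comparison test, region composition |
| `multicom.groups` | `partition_groups()` → group-specific / common SNP sets with percentages |
| `multicom.genes` | BED/GFF3 annotation, region-class precedence (CDS > 5UTR > 3UTR > exon > intronic > intergenic), candidate genes, reference-list partition |
| `multicom.enrichment` | `hypergeom_upper`, `bh_adjust`, `enrich` (GMT input) |
| `multicom.degs` | DEG table loading and category overlap with hypergeometric significance |
| `multicom.runstats` | per-sample run-metric aggregation (totals + unweighted averages) |
| `multicom.simulate` | seeded truth/caller/DEG simulator with controllable ts/tv, sensitivity, FP rate and FP intergenic bias |
| `multicom.pipeline`, `multicom.cli` | end-to-end orchestration and the `multicom` command |

## CLI

```sh
multicom simulate --seed 1 -o simdir/
multicom filter --vcf simdir/high.samtools.vcf --min-dp 5 --min-qual 30 -o filtered.vcf
multicom consensus simdir/high.*.vcf --group high --min-support 2 -o shared.vcf --report venn.tsv
multicom tstv shared.vcf --label shared
multicom tstv-compare --specific 1.60,1.79,2.38 --shared 2.61,2.63,2.65
multicom groupdiff --high high.shared.vcf --low low.shared.vcf -o prefix
multicom genes --snps prefix.high_specific.vcf --annotation simdir/annotation.gff3 -o genes_high.txt
multicom qtl-partition --high genes_high.txt --low genes_low.txt --reference qtl.txt
multicom enrich --query genes_low.txt --gmt pathways.gmt --universe universe.txt --alpha 0.01
multicom deg-overlap --deg deg.tsv --low genes_low.txt --high genes_high.txt \
    --common genes_common.txt --universe universe.txt
multicom summarize runs.tsv
multicom run --config pipeline.yaml   # full chain, JSON summary in the outdir
```

Filtering defaults are depth ≥ 5 and quality ≥ 30 (inclusive);
enrichment and DEG significance default to adjusted p < 0.01.

## Notes and known caveats

- VCF QUAL is carried at 3-decimal precision (htslib stores QUAL as a
  32-bit float); this keeps `read_vcf(write_vcf(cs)) == cs` exact.
- In the source summary table the printed 67.8 average for "Target
  covered (%)" does not equal the unweighted column mean (68.9); the
  aggregation here is unweighted, which reproduces every other printed
  total/average, and this column is excluded from golden tests.
- DEG/candidate gene matching is by case-folded symbol only — no
  orthology mapping.
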