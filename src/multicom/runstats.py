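"""Aggregation of per-sample sequencing run metrics.

Read and base counts are summed across samples; mean read lengths and
percentages are averaged unweighted over samples (mean lengths rounded
half-up to an integer, percentages to one decimal).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from multicom._util import round_half_up

__all__ = ["RunMetrics", "RunSummary", "summarize_runs", "read_run_metrics"]

COLUMNS = ("sample_id", "raw_reads", "raw_bases_mb", "raw_mean_len",
           "filt_reads", "filt_bases_mb", "filt_mean_len", "pct_passed", "pct_on_target")


@dataclass(frozen=True)
class RunMetrics:
    """One sample's raw and filtered sequencing metrics."""

    sample_id: str
    raw_reads: int
    raw_bases_mb: float
    raw_mean_len: float
    filt_reads: int
    filt_bases_mb: float
    filt_mean_len: float
    pct_passed: float
    pct_on_target: float

    def __post_init__(self) -> None:
        if self.filt_reads > self.raw_reads:
            raise ValueError(f"{self.sample_id}: filtered reads exceed raw reads")
        for name in ("pct_passed", "pct_on_target"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0, 100]")


@dataclass(frozen=True)
class RunSummary:
    n_samples: int
    total_raw_reads: int
    total_raw_bases_mb: float
    mean_raw_len: int
    total_filt_reads: int
    total_filt_bases_mb: float
    mean_filt_len: int
    mean_pct_passed: float
    mean_pct_on_target: float


def summarize_runs(rows: Sequence[RunMetrics]) -> RunSummary:
    """Totals-and-averages summary row over per-sample metrics."""
    if not rows:
        raise ValueError("no run metrics to summarize")
    n = len(rows)
    # fsum keeps float totals/averages permutation-invariant
    mean = lambda attr: math.fsum(getattr(r, attr) for r in rows) / n
    return RunSummary(
        n_samples=n,
        total_raw_reads=sum(r.raw_reads for r in rows),
        total_raw_bases_mb=math.fsum(r.raw_bases_mb for r in rows),
        mean_raw_len=int(round_half_up(mean("raw_mean_len"))),
        total_filt_reads=sum(r.filt_reads for r in rows),
        total_filt_bases_mb=math.fsum(r.filt_bases_mb for r in rows),
        mean_filt_len=int(round_half_up(mean("filt_mean_len"))),
        mean_pct_passed=round_half_up(mean("pct_passed"), 1),
        mean_pct_on_target=round_half_up(mean("pct_on_target"), 1),
    )


def read_run_metrics(path: str | os.PathLike) -> list[RunMetrics]:
    """Read a per-sample metrics TSV with the standard column order."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing run-metrics columns: {sorted(missing)}")
    return [RunMetrics(sample_id=str(r.sample_id), raw_reads=int(r.raw_reads),
                       raw_bases_mb=float(r.raw_bases_mb), raw_mean_len=float(r.raw_mean_len),
                       filt_reads=int(r.filt_reads), filt_bases_mb=float(r.filt_bases_mb),
                       filt_mean_len=float(r.filt_mean_len), pct_passed=float(r.pct_passed),
                       pct_on_target=float(r.pct_on_target))
            for r in df.itertuples(index=False)]
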