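import itertools
import math

import numpy as np
import pytest

from multicom.consensus import multicom
from multicom.groups import partition_groups
from multicom.simulate import (
    SimConfig,
    simulate_caller,
    simulate_deg,
    simulate_group,
    simulate_truth,
    write_simulation,
)
from multicom.tstv import region_composition, tstv_ratio
from multicom.variants import filter_callset, read_vcf


@pytest.fixture(scope="module")
def small_truth():
    return simulate_truth(SimConfig(seed=42, n_true_high=300, n_true_low=300,
                                    n_common_true=1400, n_genes=100))


class TestSimulateTruth:
    def test_deterministic(self):
        cfg = SimConfig(seed=5, n_true_high=50, n_true_low=50, n_common_true=100, n_genes=40)
        a, b = simulate_truth(cfg), simulate_truth(cfg)
        assert a.truth_high == b.truth_high
        assert a.truth_low == b.truth_low
        assert a.truth_common == b.truth_common

    def test_seed_changes_output(self):
        base = dict(n_true_high=50, n_true_low=50, n_common_true=100, n_genes=40)
        a = simulate_truth(SimConfig(seed=1, **base))
        b = simulate_truth(SimConfig(seed=2, **base))
        assert a.truth_high != b.truth_high

    def test_empty_high(self):
        t = simulate_truth(SimConfig(seed=0, n_true_high=0, n_true_low=10,
                                     n_common_true=10, n_genes=40))
        assert t.truth_high == frozenset()

    def test_sets_disjoint_and_sized(self, small_truth):
        assert len(small_truth.truth_high) == 300
        assert len(small_truth.truth_low) == 300
        assert len(small_truth.truth_common) == 1400
        assert not (small_truth.truth_high & small_truth.truth_low)
        assert not (small_truth.truth_high & small_truth.truth_common)

    def test_tstv_target_within_3se(self):
        cfg = SimConfig(seed=7, n_true_high=0, n_true_low=0, n_common_true=50_000,
                        genome=(("1", 8_000_000), ("2", 8_000_000)), n_genes=600)
        t = simulate_truth(cfg)
        rep = tstv_ratio(t.truth_common)
        n = rep.n
        p_target = cfg.tstv_true / (1 + cfg.tstv_true)
        se = math.sqrt(p_target * (1 - p_target) / n)
        assert abs(rep.ts / n - p_target) < 3 * se

    def test_genome_too_small(self):
        with pytest.raises(ValueError):
            simulate_truth(SimConfig(genome=(("1", 1000),), n_genes=2, gene_length=100,
                                     exon_length=20, n_true_high=5000, n_true_low=0,
                                     n_common_true=0))

    def test_intergenic_fraction_respected(self, small_truth):
        comp = region_composition(small_truth.all_truth, small_truth.annotation)
        assert comp.intergenic_fraction == pytest.approx(0.3, abs=0.05)


class TestSimulateCaller:
    def test_perfect_caller_equals_truth(self):
        cfg = SimConfig(seed=3, n_true_high=100, n_true_low=0, n_common_true=200,
                        n_genes=50, caller_sensitivity={"perfect": 1.0},
                        caller_fp_rate={"perfect": 0.0}, subthreshold_fraction=0.0)
        t = simulate_truth(cfg)
        cs = simulate_caller(t, "perfect", "high")
        assert cs.keys == t.truth_for_group("high")

    def test_dead_caller_empty(self):
        cfg = SimConfig(seed=3, n_true_high=100, n_true_low=0, n_common_true=200,
                        n_genes=50, caller_sensitivity={"dead": 0.0},
                        caller_fp_rate={"dead": 0.0})
        t = simulate_truth(cfg)
        assert len(simulate_caller(t, "dead", "high")) == 0

    def test_unknown_caller(self, small_truth):
        with pytest.raises(KeyError):
            simulate_caller(small_truth, "gatk", "high")

    def test_deterministic_per_stream(self, small_truth):
        a = simulate_caller(small_truth, "samtools", "high")
        b = simulate_caller(small_truth, "samtools", "high")
        assert a == b
        c = simulate_caller(small_truth, "freebayes", "high")
        assert a.keys != c.keys

    def test_consensus_beats_single_callers(self, small_truth):
        """k=2 precision exceeds every single caller's precision."""
        callsets = {c: filter_callset(cs) for c, cs in simulate_group(small_truth, "high").items()}
        truth = small_truth.truth_for_group("high")
        res = multicom(list(callsets.values()), 2)
        consensus_precision = len(res.shared & truth) / len(res.shared)
        for cs in callsets.values():
            single = len(cs.keys & truth) / len(cs)
            assert consensus_precision > single

    def test_shared_fp_knob_breaks_independence(self):
        cfg = SimConfig(seed=19, n_true_high=200, n_true_low=0, n_common_true=800,
                        n_genes=80, fp_shared_fraction=1.0)
        t = simulate_truth(cfg)
        callsets = [filter_callset(cs) for cs in simulate_group(t, "high").values()]
        res = multicom(callsets, 2)
        truth = t.truth_for_group("high")
        fp_shared = len(res.shared - truth)
        assert fp_shared > 0  # correlated errors leak through the consensus


@pytest.fixture(scope="module")
def gene_pools():
    universe = frozenset(f"G{i:04d}" for i in range(2000))
    candidates = frozenset(f"G{i:04d}" for i in range(400))
    return universe, candidates


class TestSimulateDeg:

    def test_deterministic_tsv(self, gene_pools, tmp_path):
        universe, candidates = gene_pools
        cfg = SimConfig(seed=9, n_deg=100, n_deg_background=100)
        a = simulate_deg(universe, candidates, cfg)
        b = simulate_deg(universe, candidates, cfg)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_csv(pa, sep="\t", index=False)
        b.to_csv(pb, sep="\t", index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_full_enrichment(self, gene_pools):
        universe, candidates = gene_pools
        cfg = SimConfig(seed=9, n_deg=100, n_deg_background=50, deg_candidate_fraction=1.0)
        df = simulate_deg(universe, candidates, cfg)
        deg = df[df.pvalue < 0.01]
        assert len(deg) == 100
        assert set(deg.gene_id) <= set(candidates)

    def test_zero_enrichment_matches_background_share(self, gene_pools):
        universe, candidates = gene_pools
        cfg = SimConfig(seed=29, n_deg=300, n_deg_background=100, deg_candidate_fraction=0.0)
        df = simulate_deg(universe, candidates, cfg)
        deg = set(df[df.pvalue < 0.01].gene_id)
        share = len(deg & set(candidates)) / len(deg)
        expected = len(candidates) / len(universe)  # 0.2 under uniform draw
        se = math.sqrt(expected * (1 - expected) / len(deg))
        assert abs(share - expected) < 4 * se

    def test_signs_balanced(self, gene_pools):
        universe, candidates = gene_pools
        cfg = SimConfig(seed=9, n_deg=100, n_deg_background=0)
        df = simulate_deg(universe, candidates, cfg)
        deg = df[df.pvalue < 0.01]
        assert abs((deg.logfc > 0).sum() - 50) <= 1

    def test_too_many_deg(self, gene_pools):
        universe, candidates = gene_pools
        with pytest.raises(ValueError):
            simulate_deg(universe, candidates, SimConfig(n_deg=1900, n_deg_background=200))


class TestEndToEnd:
    def test_pipeline_recovery(self):
        """filter -> consensus -> partition recovers >= 95% of specifics."""
        cfg = SimConfig(seed=1)
        t = simulate_truth(cfg)
        shared = {}
        for group in ("high", "low"):
            callsets = [filter_callset(cs) for cs in simulate_group(t, group).values()]
            shared[group] = multicom(callsets, 2).shared
        part = partition_groups(shared["high"], shared["low"])
        rec_high = len(part.specific_high & t.truth_high) / len(t.truth_high)
        rec_low = len(part.specific_low & t.truth_low) / len(t.truth_low)
        assert rec_high >= 0.95
        assert rec_low >= 0.95


def test_write_simulation_artifacts(tmp_path):
    cfg = SimConfig(seed=2, n_true_high=60, n_true_low=60, n_common_true=280, n_genes=60,
                    n_deg=20, n_deg_background=20)
    t = simulate_truth(cfg)
    paths = write_simulation(t, tmp_path / "sim")
    cs = read_vcf(paths["vcf:high:samtools"], caller="samtools", group="high")
    assert cs == simulate_group(t, "high")["samtools"]
    assert (tmp_path / "sim" / "annotation.gff3").exists()
    assert (tmp_path / "sim" / "deg.tsv").exists()
    manifest = (tmp_path / "sim" / "truth_manifest.tsv").read_text().splitlines()
    assert len(manifest) == 1 + cfg.n_truth
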