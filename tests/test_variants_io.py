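import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multicom.variants import (
    Callset,
    VariantKey,
    VariantRecord,
    VcfParseError,
    filter_callset,
    normalize_chrom,
    read_vcf,
    union_callsets,
    write_vcf,
)


class TestVariantKey:
    def test_valid(self):
        k = VariantKey("1", 100, "A", "G")
        assert (k.chrom, k.pos, k.ref, k.alt) == ("1", 100, "A", "G")

    @pytest.mark.parametrize("kwargs", [
        dict(chrom="1", pos=0, ref="A", alt="G"),
        dict(chrom="1", pos=5, ref="A", alt="A"),
        dict(chrom="1", pos=5, ref="N", alt="G"),
        dict(chrom="1", pos=5, ref="AT", alt="G"),
        dict(chrom="1", pos=5, ref="a", alt="G"),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)

    def test_chrom_normalization(self):
        assert normalize_chrom("chr1") == "1"
        assert normalize_chrom("Chr1") == "1"
        assert normalize_chrom("1") == "1"
        assert normalize_chrom("chr") == "chr"  # no suffix to keep


class TestVariantRecord:
    def test_negative_values_rejected(self):
        k = VariantKey("1", 1, "A", "G")
        with pytest.raises(ValueError):
            VariantRecord(key=k, qual=-1.0, depth=5)
        with pytest.raises(ValueError):
            VariantRecord(key=k, qual=5.0, depth=-1)

    def test_missing_allowed(self):
        k = VariantKey("1", 1, "A", "G")
        rec = VariantRecord(key=k, qual=None, depth=None)
        assert rec.qual is None and rec.depth is None


class TestReadVcf:
    def test_single_snp(self, vcf_file):
        cs = read_vcf(vcf_file(["chr1 100 . A G 40 . DP=10"]), caller="c", group="g")
        assert len(cs) == 1
        rec = next(iter(cs))
        assert rec.key == VariantKey("1", 100, "A", "G")
        assert rec.qual == 40.0
        assert rec.depth == 10

    def test_multiallelic_split(self, vcf_file):
        cs = read_vcf(vcf_file(["chr1 200 . A G,T 40 . DP=10"]))
        assert cs.keys == {VariantKey("1", 200, "A", "G"), VariantKey("1", 200, "A", "T")}

    def test_indel_dropped_and_counted(self, vcf_file):
        cs = read_vcf(vcf_file(["chr1 300 . AT A 40 . DP=10"]))
        assert len(cs) == 0
        assert cs.meta["n_dropped_non_snp"] == 1

    def test_mixed_alleles_preserve_total_alt_count(self, vcf_file):
        cs = read_vcf(vcf_file(["chr1 300 . A G,AT,C 40 . DP=10"]))
        assert len(cs) + cs.meta["n_dropped_non_snp"] == 3
        assert len(cs) == 2

    def test_missing_dp_flagged(self, vcf_file):
        cs = read_vcf(vcf_file(["chr1 100 . A G 40 . ."]))
        rec = next(iter(cs))
        assert rec.depth is None
        # missing depth always fails the depth filter
        assert len(filter_callset(cs, min_depth=1, min_qual=0)) == 0

    def test_sample_dp_fallback(self, tmp_path):
        path = tmp_path / "samples.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t10\t.\tA\tG\t40\t.\t.\tDP\t4\t7\n")
        rec = next(iter(read_vcf(path)))
        assert rec.depth == 11

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_vcf(tmp_path / "nope.vcf")

    def test_not_a_vcf(self, tmp_path):
        path = tmp_path / "junk.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(VcfParseError):
            read_vcf(path)


class TestFilterCallset:
    def test_boundary_inclusive(self):
        k = [VariantKey("1", i, "A", "G") for i in (1, 2, 3)]
        cs = Callset.from_records("c", "g", [
            VariantRecord(key=k[0], qual=30.0, depth=5),
            VariantRecord(key=k[1], qual=99.0, depth=4),
            VariantRecord(key=k[2], qual=29.0, depth=99),
        ])
        out = filter_callset(cs, min_depth=5, min_qual=30)
        assert out.keys == {k[0]}
        assert out.meta["filter"]["n_failed_depth"] == 1
        assert out.meta["filter"]["n_failed_qual"] == 1

    def test_empty_and_identity(self):
        empty = Callset.from_records("c", "g", [])
        assert len(filter_callset(empty, 5, 30)) == 0
        cs = Callset.from_records("c", "g", [
            VariantRecord(key=VariantKey("1", 1, "A", "G"), qual=0.0, depth=0)])
        assert filter_callset(cs, 0, 0) == cs

    def test_idempotent(self):
        cs = Callset.from_records("c", "g", [
            VariantRecord(key=VariantKey("1", i, "C", "T"), qual=float(q), depth=d)
            for i, (q, d) in enumerate([(50, 9), (10, 9), (50, 2), (31, 5)], start=1)])
        once = filter_callset(cs, 5, 30)
        twice = filter_callset(once, 5, 30)
        assert once == twice

    def test_negative_threshold_rejected(self):
        cs = Callset.from_records("c", "g", [])
        with pytest.raises(ValueError):
            filter_callset(cs, -1, 30)

    def test_input_unmodified(self):
        cs = Callset.from_records("c", "g", [
            VariantRecord(key=VariantKey("1", 1, "A", "G"), qual=1.0, depth=1)])
        filter_callset(cs, 5, 30)
        assert len(cs) == 1


class TestWriteVcf:
    def test_round_trip(self, tmp_path):
        cs = Callset.from_records("samtools", "high", [
            VariantRecord(key=VariantKey("2", 5, "C", "T"), qual=31.5, depth=8),
            VariantRecord(key=VariantKey("1", 9, "G", "A"), qual=99.0, depth=44),
            VariantRecord(key=VariantKey("1", 9, "G", "C"), qual=12.25, depth=3),
        ])
        path = tmp_path / "out.vcf"
        write_vcf(cs, path)
        assert read_vcf(path, caller="samtools", group="high") == cs

    def test_empty_callset_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf(Callset.from_records("c", "g", []), path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []
        assert len(read_vcf(path)) == 0

    def test_output_sorted(self, tmp_path):
        cs = Callset.from_records("c", "g", [
            VariantRecord(key=VariantKey("2", 1, "A", "G"), qual=1.0, depth=1),
            VariantRecord(key=VariantKey("1", 7, "A", "T"), qual=1.0, depth=1),
            VariantRecord(key=VariantKey("1", 7, "A", "C"), qual=1.0, depth=1),
        ])
        path = tmp_path / "sorted.vcf"
        write_vcf(cs, path)
        body = [l.split("\t") for l in path.read_text().splitlines() if not l.startswith("#")]
        assert [(f[0], int(f[1]), f[4]) for f in body] == [("1", 7, "C"), ("1", 7, "T"), ("2", 1, "G")]


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.integers(1, 500),
              st.sampled_from([("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]),
              st.one_of(st.none(), st.floats(0, 5000).map(lambda q: round(q, 2))),
              st.one_of(st.none(), st.integers(0, 1000))),
    unique_by=lambda t: (t[0], t[1]), max_size=40))
def test_round_trip_property(tmp_path_factory, entries):
    """read(write(x)) == x for arbitrary valid callsets."""
    cs = Callset.from_records("c", "g", [
        VariantRecord(key=VariantKey("1", pos, ra[0], ra[1]), qual=q, depth=d)
        for pos, ra, q, d in entries])
    path = tmp_path_factory.mktemp("rt") / "cs.vcf"
    write_vcf(cs, path)
    assert read_vcf(path, caller="c", group="g") == cs


def test_union_callsets_keeps_best_record():
    a = Callset.from_records("s", "high", [
        VariantRecord(key=VariantKey("1", 1, "A", "G"), qual=10.0, depth=5)])
    b = Callset.from_records("s", "high", [
        VariantRecord(key=VariantKey("1", 1, "A", "G"), qual=90.0, depth=5),
        VariantRecord(key=VariantKey("1", 2, "C", "T"), qual=50.0, depth=9)])
    pooled = union_callsets([a, b], caller="s", group="high")
    assert len(pooled) == 2
    assert pooled.records[VariantKey("1", 1, "A", "G")].qual == 90.0


def test_duplicate_key_rejected():
    rec = VariantRecord(key=VariantKey("1", 1, "A", "G"), qual=1.0, depth=1)
    with pytest.raises(ValueError, match="duplicate"):
        Callset.from_records("c", "g", [rec, rec])


def test_empty_labels_rejected():
    with pytest.raises(ValueError):
        Callset.from_records("", "g", [])
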