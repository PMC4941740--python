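import pytest

from multicom.variants import Callset, VariantKey, VariantRecord

BASES = "ACGT"


def key(i: int, chrom: str = "1", ref: str = "A", alt: str = "G") -> VariantKey:
    """Deterministic VariantKey for an integer label."""
    return VariantKey(chrom, int(i), ref, alt)


def keyset(labels) -> frozenset:
    return frozenset(key(i) for i in labels)


def make_callset(caller, group, labels, qual=50.0, depth=10) -> Callset:
    return Callset.from_records(
        caller, group,
        (VariantRecord(key=key(i), qual=qual, depth=depth) for i in labels))


@pytest.fixture
def vcf_file(tmp_path):
    """Write VCF body lines (CHROM..INFO columns) to a file; returns the path."""

    def write(lines, name="test.vcf", header_extra=()):
        path = tmp_path / name
        header = ["##fileformat=VCFv4.2",
                  '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
                  *header_extra,
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        path.write_text("\n".join(header + [l.replace(" ", "\t") for l in lines]) + "\n")
        return path

    return write
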