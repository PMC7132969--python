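import pytest
from hypothesis import settings

from exonscout.genomic_io import GeneModel, GenomicInterval
from exonscout.synthetic_data import LocusSpec, simulate_locus

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def locus():
    """The default synthetic locus (7 exons, planted 386 bp intronic exon)."""
    return simulate_locus(LocusSpec())


@pytest.fixture()
def two_exon_gene():
    """Minimal gene: exons at [100,150) and [500,560) on one transcript."""
    exons = [
        GenomicInterval("chr1", 100, 150, "+"),
        GenomicInterval("chr1", 500, 560, "+"),
    ]
    return GeneModel("g1", "+", exons, {"t1": [0, 1]})


def write_sam(path, records, chrom="chr1", length=100_000):
    """Write a minimal headered SAM file.

    ``records`` is an iterable of (name, flag, pos_1based, mapq, cigar).
    """
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for name, flag, pos, mapq, cigar in records:
        lines.append(
            f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
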