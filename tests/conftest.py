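import numpy as np
import pytest

from bsamap.calling import SNPRecord
from bsamap.genome import GeneModel, ReferenceGenome, generate_toy_genome, reverse_complement


@pytest.fixture(scope="session")
def toy():
    """Small deterministic genome with gene models, reused across tests."""
    genome, models = generate_toy_genome(2, 60_000, 6, seed=11, n_codons=100)
    return genome, models


def build_gene(coding: str, strand: str, chrom: str = "chrX", flank: int = 50,
               utr_len: int = 12):
    """Single-exon gene embedding a given coding sequence, with UTRs and flanks.

    Returns (genome, model). For a minus-strand gene the genomic sequence holds
    the reverse complement of ``coding`` and the 5'UTR sits genomically after
    the CDS.
    """
    assert len(coding) % 3 == 0
    cds_genomic = coding if strand == "+" else reverse_complement(coding)
    seq = "A" * flank + "G" * utr_len + cds_genomic + "G" * utr_len + "A" * flank
    gstart = flank + 1
    cds_start = flank + utr_len + 1
    cds_end = cds_start + len(coding) - 1
    gend = cds_end + utr_len
    utr_a = [(gstart, cds_start - 1)]
    utr_b = [(cds_end + 1, gend)]
    model = GeneModel(
        accession="TESTG1.1", chrom=chrom, strand=strand, start=gstart, end=gend,
        cds=[(cds_start, cds_end)],
        utr5=utr_a if strand == "+" else utr_b,
        utr3=utr_b if strand == "+" else utr_a,
    )
    return ReferenceGenome({chrom: seq}), model


def coding_to_genomic(model: GeneModel, coding_index: int) -> int:
    """Genomic position of a 0-based coding index for a single-exon model."""
    (s, e), = model.cds
    if model.strand == "+":
        return s + coding_index
    return e - coding_index


@pytest.fixture(scope="session")
def table1_records():
    """The six printed candidate SNPs of the worked real-data example
    (chromosome 3; Ch_D as printed at 2 dp)."""
    rows = [
        ("3", 82825, "C", "T", "T", 52, 0.94),
        ("3", 1405085, "C", "T", "T", 31, 1.0),
        ("3", 3057628, "C", "T", "T", 45, 0.98),
        ("3", 4919240, "C", "Y", "T", 36, 0.86),
        ("3", 5482374, "C", "Y", "T", 42, 0.88),
        ("3", 6035523, "C", "Y", "T", 47, 0.85),
    ]
    return [
        SNPRecord(chrom, pos, ref, call, alt, depth, chd, float("nan"))
        for chrom, pos, ref, call, alt, depth, chd in rows
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
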