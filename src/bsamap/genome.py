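"""Reference genome and gene-model containers, FASTA/GFF3 I/O, toy-genome generation.

Coordinates are 1-based inclusive throughout, matching GFF3. Gene models are
strand-aware: CDS/UTR segments are stored in ascending genomic order regardless
of strand, and reverse-complementation happens only when coding sequence or
codons are extracted.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceGenome",
    "GeneModel",
    "CodonTable",
    "OutsideGeneError",
    "OutsideCDSError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "extract_codon",
    "cds_sequence",
    "generate_toy_genome",
]

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    """Complement one base, IUPAC ambiguity codes included (Y<->R etc.)."""
    return base.translate(_COMPLEMENT)


class OutsideGeneError(ValueError):
    """Position not covered by the gene span."""


class OutsideCDSError(ValueError):
    """Position inside the gene span but not in any CDS segment."""


@dataclass
class ReferenceGenome:
    """Ordered collection of chromosome sequences over {A,C,G,T} (uppercase).

    Non-ACGT symbols are preserved but flagged; downstream statistics skip
    such sites.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            self.chromosomes[name] = seq.upper()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.chromosomes[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside {chrom} (length {len(seq)})")
        return seq[pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        if start < 1 or end < start:
            raise ValueError(f"bad interval [{start}, {end}]")
        return self.chromosomes[chrom][start - 1 : end]

    def non_acgt_sites(self) -> dict[str, int]:
        """Per-chromosome count of non-ACGT reference symbols."""
        out = {}
        for name, seq in self.chromosomes.items():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            out[name] = int(len(arr) - np.isin(arr, [b"A", b"C", b"G", b"T"]).sum())
        return out


@dataclass
class GeneModel:
    """One mRNA: gene span plus CDS and UTR segments (1-based inclusive).

    ``codable`` is False when the total CDS length is not divisible by 3;
    such models are excluded from codon-level annotation but still count as
    genic for filtering.
    """

    accession: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    codable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds = sorted(tuple(seg) for seg in self.cds)
        self.utr5 = sorted(tuple(seg) for seg in self.utr5)
        self.utr3 = sorted(tuple(seg) for seg in self.utr3)
        for s, e in self.cds + self.utr5 + self.utr3:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"{self.accession}: segment ({s},{e}) outside gene span "
                    f"({self.start},{self.end})"
                )
        for (_, e0), (s1, _) in zip(self.cds, self.cds[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.accession}: overlapping CDS segments")
        if self.cds_length % 3 != 0:
            self.codable = False

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def region_of(self, pos: int) -> str:
        """Region label at a genomic position: CDS, 5'UTR, 3'UTR or intron."""
        if not self.contains(pos):
            raise OutsideGeneError(f"{pos} outside {self.accession}")
        for s, e in self.cds:
            if s <= pos <= e:
                return "CDS"
        for s, e in self.utr5:
            if s <= pos <= e:
                return "5'UTR"
        for s, e in self.utr3:
            if s <= pos <= e:
                return "3'UTR"
        return "intron"

    def coding_index(self, pos: int) -> int:
        """0-based position within the spliced coding sequence (strand-aware)."""
        if not self.contains(pos):
            raise OutsideGeneError(f"{pos} outside gene {self.accession}")
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                idx_fwd = offset + (pos - s)
                if self.strand == "+":
                    return idx_fwd
                return self.cds_length - 1 - idx_fwd
            offset += e - s + 1
        raise OutsideCDSError(f"{pos} in {self.accession} but outside its CDS")


class CodonTable:
    """64-entry codon -> amino-acid map; stops map to '*'."""

    def __init__(self, table: dict[str, str]):
        if len(table) != 64:
            raise ValueError(f"codon table must have 64 entries, got {len(table)}")
        self._table = dict(table)

    @classmethod
    def standard(cls) -> "CodonTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[1]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        return cls(table)

    def __getitem__(self, codon: str) -> str:
        return self._table[codon.upper()]

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        if codon not in self._table:
            raise KeyError(f"invalid codon {codon!r}")
        return self._table[codon]

    def translate_cds(self, seq: str) -> str:
        if len(seq) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        return "".join(self.translate(seq[i : i + 3]) for i in range(0, len(seq), 3))


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA file into a ReferenceGenome (order preserved, uppercased)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        chroms[rec.id] = seq
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(chroms)


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


_UTR5_TYPES = {"five_prime_UTR", "5'UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3'UTR"}


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/CDS/UTR features into GeneModels (one per mRNA).

    CDS phase is ignored; minus-strand segments keep ascending genomic
    coordinates. A model whose CDS length is not divisible by 3 is kept but
    flagged non-codable (with a warning).
    """
    import gffutils

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: {line!r}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        cds, utr5, utr3 = [], [], []
        for child in db.children(mrna, order_by="start"):
            seg = (child.start, child.end)
            if child.featuretype == "CDS":
                cds.append(seg)
            elif child.featuretype in _UTR5_TYPES:
                utr5.append(seg)
            elif child.featuretype in _UTR3_TYPES:
                utr3.append(seg)
        model = GeneModel(
            accession=mrna.id, chrom=mrna.seqid, strand=mrna.strand,
            start=mrna.start, end=mrna.end, cds=cds, utr5=utr5, utr3=utr3,
        )
        if not model.codable:
            warnings.warn(
                f"{model.accession}: CDS length {model.cds_length} not divisible "
                "by 3; model marked non-codable"
            )
        models.append(model)
    return models


def write_gff3(models: list[GeneModel], path: str | os.PathLike) -> None:
    """Serialize GeneModels as gene/mRNA/CDS/UTR features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene_id = m.accession.split(".")[0]
            base = f"{m.chrom}\ttoy\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(f"{base}gene\t{m.start}\t{m.end}{tail}.\tID={gene_id}\n")
            fh.write(
                f"{base}mRNA\t{m.start}\t{m.end}{tail}.\t"
                f"ID={m.accession};Parent={gene_id}\n"
            )
            for s, e in m.utr5:
                fh.write(f"{base}five_prime_UTR\t{s}\t{e}{tail}.\tParent={m.accession}\n")
            for s, e in m.cds:
                fh.write(f"{base}CDS\t{s}\t{e}{tail}0\tParent={m.accession}\n")
            for s, e in m.utr3:
                fh.write(f"{base}three_prime_UTR\t{s}\t{e}{tail}.\tParent={m.accession}\n")


def cds_sequence(genome: ReferenceGenome, model: GeneModel) -> str:
    """Spliced coding sequence in coding orientation (ATG...stop for a clean model)."""
    parts = [genome.slice(model.chrom, s, e) for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def extract_codon(
    genome: ReferenceGenome, model: GeneModel, pos: int
) -> tuple[str, int, int]:
    """Reference codon covering a genomic position inside the CDS.

    Returns ``(ref_codon, offset_in_codon, coding_index)`` where the codon is
    given in coding-strand orientation (reverse-complemented for minus-strand
    models) and ``offset_in_codon`` is 0, 1 or 2.
    """
    if not model.codable:
        raise ValueError(f"{model.accession} is non-codable (CDS length % 3 != 0)")
    cidx = model.coding_index(pos)  # raises Outside{Gene,CDS}Error
    seq = cds_sequence(genome, model)
    codon_i, offset = divmod(cidx, 3)
    return seq[3 * codon_i : 3 * codon_i + 3], offset, cidx


# --- toy genome generation -------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_cds(n_codons: int, rng: np.random.Generator, table: CodonTable) -> str:
    """ATG + random non-stop codons + one stop codon, length 3*n_codons."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons (start, one internal, stop)")
    sense = sorted(c for c in table._table if table._table[c] != "*")
    stops = sorted(c for c in table._table if table._table[c] == "*")
    internal = rng.choice(len(sense), size=n_codons - 2)
    body = "".join(sense[i] for i in internal)
    stop = stops[rng.integers(len(stops))]
    return "ATG" + body + stop


def generate_toy_genome(
    n_chrom: int,
    chrom_length: int,
    n_genes: int,
    seed: int | np.random.Generator,
    *,
    n_codons: int = 600,
    utr5_len: int = 150,
    utr3_len: int = 200,
    intron_len: int = 200,
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random genome with non-overlapping two-exon genes and clean ORFs.

    Defaults give ~2.35 kb gene spans (600-codon CDS split by one intron,
    flanked by UTRs). Deterministic for a fixed seed.
    """
    if n_chrom < 1 or chrom_length < 1 or n_genes < 1:
        raise ValueError("n_chrom, chrom_length and n_genes must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = CodonTable.standard()

    cds_len = 3 * n_codons
    span = utr5_len + cds_len + intron_len + utr3_len
    per_chrom = [n_genes // n_chrom + (i < n_genes % n_chrom) for i in range(n_chrom)]

    chroms: dict[str, str] = {}
    models: list[GeneModel] = []
    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        seq = rng.choice(_BASES, size=chrom_length).tobytes().decode()
        arr = list(seq)
        k = per_chrom[ci]
        gap = 10  # minimum spacer between genes and from chromosome ends
        free = chrom_length - k * (span + gap) - gap
        if free <= 0:
            raise ValueError(
                f"cannot place {k} genes of span {span} on a {chrom_length} bp chromosome"
            )
        offsets = np.sort(rng.integers(0, free, size=k))
        starts = offsets + gap + 1 + np.arange(k) * (span + gap)
        for gi, gstart in enumerate(starts):
            gstart = int(gstart)
            gend = gstart + span - 1
            strand = "+" if rng.integers(2) == 0 else "-"
            # segment layout in genomic order: UTRa, exon1, intron, exon2, UTRb
            exon1_len = (cds_len // 2 // 3) * 3  # keep split at a codon boundary
            exon1 = (gstart + utr5_len, gstart + utr5_len + exon1_len - 1)
            exon2 = (exon1[1] + intron_len + 1, exon1[1] + intron_len + (cds_len - exon1_len))
            utr_a = (gstart, gstart + utr5_len - 1)
            utr_b = (exon2[1] + 1, gend)
            if strand == "+":
                utr5, utr3 = [utr_a], [utr_b]
            else:
                utr5, utr3 = [utr_b], [utr_a]
            coding = _random_cds(n_codons, rng, table)
            # lay the coding sequence over the CDS positions in coding order
            genomic_positions: list[int] = []
            for s, e in (exon1, exon2):
                genomic_positions.extend(range(s, e + 1))
            if strand == "-":
                genomic_positions = genomic_positions[::-1]
            for base, gpos in zip(coding, genomic_positions):
                arr[gpos - 1] = base if strand == "+" else complement_base(base)
            acc = f"TOY{ci + 1}G{gi + 1:04d}.1"
            models.append(
                GeneModel(
                    accession=acc, chrom=name, strand=strand,
                    start=gstart, end=gend, cds=[exon1, exon2],
                    utr5=utr5, utr3=utr3,
                )
            )
        chroms[name] = "".join(arr)
    return ReferenceGenome(chroms), models
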