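"""Strand-aware codon-effect annotation of SNPs against gene models.

Conventions follow the field's tabular reporting of candidate SNPs:
codons are given in coding-strand orientation; a heterozygous-like IUPAC
call substituted into a codon leaves the amino-acid change blank ("P ->"),
because the SNP base is not resolved to a discrete nucleotide — even when
every resolution of the ambiguous codon is synonymous, the blank is kept
(the convention is lexical, not semantic). For minus-strand genes the called
base is complemented before substitution, ambiguity codes code-wise (Y<->R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

from .genome import (
    CodonTable,
    GeneModel,
    OutsideCDSError,
    ReferenceGenome,
    complement_base,
    extract_codon,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SnpAnnotation",
    "GeneIndex",
    "classify_region",
    "classify_effect",
    "annotate_codon_change",
    "annotate_snp",
    "annotate_records",
    "EFFECT_SEVERITY",
]

AMBIGUOUS = set("RYSWKM")

#: ranking order used for tie-breaks among equal-Ch_D candidates
EFFECT_SEVERITY = {
    "stop-gain": 5,
    "stop-loss": 4,
    "missense": 3,
    "synonymous": 2,
    "ambiguous": 2,
    "noncoding": 1,
}

_CODON_TABLE = CodonTable.standard()


@dataclass
class SnpAnnotation:
    """Codon-level annotation of one SNP (Table-style columns)."""

    accession: str | None
    region: str  # CDS, 5'UTR, 3'UTR, intron, intergenic
    ref_codon: str = ""
    snp_codon: str = ""
    aa_change: str = ""
    effect: str = "noncoding"

    @property
    def severity(self) -> int:
        return EFFECT_SEVERITY[self.effect]


class GeneIndex:
    """Interval index of gene spans for genic lookup and region classification."""

    def __init__(self, models: list[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(m.start, m.end + 1, m)  # interval end is exclusive

    @property
    def n_genes(self) -> int:
        return len(self.models)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        return sorted(hits, key=lambda m: m.accession)


def classify_region(
    chrom: str, pos: int, gene_index: GeneIndex
) -> tuple[str, str | None]:
    """Region label and accession at a position; intergenic when in no gene.

    When several genes overlap the position the lowest accession wins and the
    overlap is logged.
    """
    hits = gene_index.overlapping(chrom, pos)
    if not hits:
        return "intergenic", None
    if len(hits) > 1:
        logger.info("position %s:%d overlaps %d genes; annotating against %s",
                    chrom, pos, len(hits), hits[0].accession)
    model = hits[0]
    return model.region_of(pos), model.accession


def classify_effect(ref_codon: str, snp_codon: str, table: CodonTable | None = None) -> str:
    """Effect class of a codon substitution; 'ambiguous' when the SNP codon
    contains an ambiguity code and cannot be resolved to one codon."""
    table = table or _CODON_TABLE
    for codon in (ref_codon, snp_codon):
        if len(codon) != 3:
            raise ValueError(f"invalid codon {codon!r}")
    if any(b in AMBIGUOUS for b in snp_codon):
        return "ambiguous"
    aa_ref, aa_snp = table.translate(ref_codon), table.translate(snp_codon)
    if aa_ref == aa_snp:
        return "synonymous"
    if aa_snp == "*":
        return "stop-gain"
    if aa_ref == "*":
        return "stop-loss"
    return "missense"


def annotate_codon_change(
    chrom: str,
    pos: int,
    alt_call: str,
    model: GeneModel,
    genome: ReferenceGenome,
    table: CodonTable | None = None,
) -> SnpAnnotation:
    """Codon-level annotation of a CDS SNP (``alt_call`` may be an IUPAC code)."""
    table = table or _CODON_TABLE
    ref_codon, offset, _ = extract_codon(genome, model, pos)
    alt_c = alt_call if model.strand == "+" else complement_base(alt_call)
    snp_codon = ref_codon[:offset] + alt_c + ref_codon[offset + 1 :]
    effect = classify_effect(ref_codon, snp_codon, table)
    aa_ref = table.translate(ref_codon)
    if effect == "ambiguous":
        aa_change = f"{aa_ref} →"  # unresolved base: blank right-hand side
    else:
        aa_change = f"{aa_ref} → {table.translate(snp_codon)}"
    return SnpAnnotation(
        accession=model.accession, region="CDS",
        ref_codon=ref_codon, snp_codon=snp_codon,
        aa_change=aa_change, effect=effect,
    )


def annotate_snp(
    chrom: str,
    pos: int,
    alt_call: str,
    gene_index: GeneIndex,
    genome: ReferenceGenome,
    table: CodonTable | None = None,
) -> SnpAnnotation:
    """Full annotation of one SNP: region, and codon change when in a CDS.

    Overlapping genes are all considered and the most severe effect reported.
    """
    hits = gene_index.overlapping(chrom, pos)
    if not hits:
        return SnpAnnotation(accession=None, region="intergenic")
    annotations = []
    for model in hits:
        region = model.region_of(pos)
        if region == "CDS" and model.codable:
            try:
                annotations.append(annotate_codon_change(chrom, pos, alt_call, model, genome, table))
                continue
            except OutsideCDSError:  # pragma: no cover - region check precedes
                pass
        annotations.append(SnpAnnotation(accession=model.accession, region=region))
    annotations.sort(key=lambda a: (-a.severity, a.accession))
    if len(annotations) > 1:
        logger.info("position %s:%d overlaps %d genes; reporting most severe (%s)",
                    chrom, pos, len(annotations), annotations[0].accession)
    return annotations[0]


def annotate_records(
    records, gene_index: GeneIndex, genome: ReferenceGenome
) -> dict[tuple[str, int], SnpAnnotation]:
    """Annotate a list of SNPRecords, keyed by (chrom, pos)."""
    return {
        (r.chrom, r.pos): annotate_snp(r.chrom, r.pos, r.alt_call, gene_index, genome)
        for r in records
    }


def write_annotation_tsv(records, annotations, path, decimals: int = 2) -> None:
    """Candidate table mirroring the standard report columns."""
    cols = ["chrom", "pos", "ref", "snp_base", "depth", "chd", "accession",
            "region", "ref_codon", "snp_codon", "aa_change"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            a = annotations[(r.chrom, r.pos)]
            fh.write("\t".join([
                r.chrom, str(r.pos), r.ref, r.alt_call, str(r.depth),
                f"{round(r.chd, decimals):g}", a.accession or "",
                a.region, a.ref_codon, a.snp_codon, a.aa_change,
            ]) + "\n")
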