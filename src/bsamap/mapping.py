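"""The mapping mathematics: discordant chastity, allele frequency, parental
and genic filtering, thresholding, candidate ranking, segregation test, and
the versioned emap-dialect I/O.

Discordant chastity (Ch_D) is the purity statistic of the pooled sample at a
variant site: the count of the most frequent non-reference base divided by
the summed counts of the two most common bases. Ch_D = 1 indicates a
homozygous non-reference state — under perfect phenotypic selection, the
signature of the causal mutation and of markers fully linked to it. The
mutant allele frequency (AF) is the mutant-allele read count over total depth;
the two coincide at biallelic sites whose top base is non-reference.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

from .seqsim import BASES, SiteCounts

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import SnpAnnotation
    from .calling import SNPRecord

__all__ = [
    "MappingConfig",
    "CandidateReport",
    "discordant_chastity",
    "allele_frequency",
    "filter_parental",
    "filter_genic",
    "threshold_candidates",
    "rank_candidates",
    "segregation_chi_square",
    "write_emap",
    "read_emap",
]

EMAP_DIALECT_VERSION = "1"

#: returned where a statistic is undefined (depth 0); such sites are skipped
UNDEFINED = float("nan")


@dataclass
class MappingConfig:
    chd_threshold: float = 0.85
    genic_only: bool = True
    parent_match_mode: str = "position+allele"
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.chd_threshold <= 1.0:
            raise ValueError("chd_threshold must be in [0, 1]")
        if self.parent_match_mode not in {"position", "position+allele"}:
            raise ValueError(f"bad parent_match_mode {self.parent_match_mode!r}")


def _counts_items(counts) -> list[tuple[str, int]]:
    if isinstance(counts, SiteCounts):
        return [(b, counts.counts[b]) for b in BASES]
    return [(b, int(counts.get(b, 0))) for b in BASES]


def discordant_chastity(counts, ref: str) -> float:
    """Ch_D = N(top non-reference base) / (N(top base) + N(second base)).

    0 when no non-reference base is observed; 1 when the only observed base
    is non-reference; NaN (undefined) at depth 0.
    """
    items = _counts_items(counts)
    values = sorted((n for _, n in items), reverse=True)
    depth = sum(values)
    if depth == 0:
        return UNDEFINED
    top_nonref = max(n for b, n in items if b != ref)
    if top_nonref == 0:
        return 0.0
    return top_nonref / (values[0] + values[1])


def allele_frequency(counts, alt_base: str) -> float:
    """Mutant allele frequency: N(alt) / depth; NaN at depth 0."""
    items = dict(_counts_items(counts))
    depth = sum(items.values())
    if depth == 0:
        return UNDEFINED
    return items[alt_base] / depth


def _check_sorted(records, name: str) -> None:
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError(f"{name} records must be sorted by (chrom, pos)")


def filter_parental(
    mutant_records: list["SNPRecord"],
    parent_records: list["SNPRecord"],
    mode: str = "position+allele",
) -> list["SNPRecord"]:
    """Remove variants also called in the parent sample.

    ``position`` matches by site alone; ``position+allele`` (default, stricter
    in what it retains) also requires the same discrete alternate base, so a
    mutant-specific allele at a coincident position survives.
    """
    if mode not in {"position", "position+allele"}:
        raise ValueError(f"bad mode {mode!r}")
    _check_sorted(mutant_records, "mutant")
    _check_sorted(parent_records, "parent")
    if mode == "position":
        parent_keys = {(r.chrom, r.pos) for r in parent_records}
        return [r for r in mutant_records if (r.chrom, r.pos) not in parent_keys]
    parent_keys = {(r.chrom, r.pos, r.alt_base) for r in parent_records}
    return [r for r in mutant_records if (r.chrom, r.pos, r.alt_base) not in parent_keys]


def filter_genic(records: list["SNPRecord"], gene_models) -> list["SNPRecord"]:
    """Keep records falling within any gene span (UTRs and introns included)."""
    import warnings

    from .annotate import GeneIndex

    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    if index.n_genes == 0:
        warnings.warn("no gene models: genic filter removes every SNP")
        return []
    return [r for r in records if index.overlapping(r.chrom, r.pos)]


def threshold_candidates(records: list["SNPRecord"], chd_threshold: float) -> list["SNPRecord"]:
    """Records whose Ch_D is at or above the threshold (NaN never passes)."""
    return [r for r in records if not math.isnan(r.chd) and r.chd >= chd_threshold]


@dataclass
class CandidateReport:
    """Ranked candidate list: Ch_D descending, then effect severity, then position."""

    entries: list[tuple["SNPRecord", "SnpAnnotation", int]] = field(default_factory=list)
    chd_threshold: float = 0.85

    @property
    def best(self):
        if not self.entries:
            return None
        return self.entries[0][0]

    @property
    def no_candidate(self) -> bool:
        return not self.entries

    def __len__(self) -> int:
        return len(self.entries)


def rank_candidates(
    records: list["SNPRecord"],
    annotations: dict[tuple[str, int], "SnpAnnotation"],
    chd_threshold: float = 0.85,
) -> CandidateReport:
    """Rank candidates by (Ch_D desc, effect severity desc, position asc)."""
    import warnings

    if not records:
        warnings.warn("no candidate at threshold: empty candidate list")
        return CandidateReport([], chd_threshold)
    def key(r):
        ann = annotations[(r.chrom, r.pos)]
        return (-r.chd, -ann.severity, r.chrom, r.pos)
    ordered = sorted(records, key=key)
    entries = [
        (r, annotations[(r.chrom, r.pos)], i + 1) for i, r in enumerate(ordered)
    ]
    return CandidateReport(entries, chd_threshold)


def segregation_chi_square(
    n_mutant: int, n_wildtype: int, expected_ratio: tuple[int, int] = (1, 3)
) -> tuple[float, float]:
    """1-df chi-square of observed mutant:wild-type counts against an expected
    segregation ratio (default 1:3, a single recessive causal locus)."""
    if n_mutant < 0 or n_wildtype < 0:
        raise ValueError("counts must be non-negative")
    total = n_mutant + n_wildtype
    if total == 0:
        raise ValueError("both counts are zero")
    w = expected_ratio[0] + expected_ratio[1]
    f_exp = [total * expected_ratio[0] / w, total * expected_ratio[1] / w]
    res = stats.chisquare([n_mutant, n_wildtype], f_exp=f_exp)
    return float(res.statistic), float(res.pvalue)


# --- emap dialect ----------------------------------------------------------

def write_emap(
    records: list["SNPRecord"], path: str | os.PathLike, meta: dict | None = None
) -> None:
    """Write the versioned emap dialect: ``chrom pos ref alt_call depth chd``
    with provenance header lines; chd at full precision (reports round later)."""
    with open(path, "w") as fh:
        fh.write(f"# emap_dialect={EMAP_DIALECT_VERSION}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("chrom\tpos\tref\talt_call\tdepth\tchd\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt_call}\t{r.depth}\t{r.chd!r}\n")


def read_emap(path: str | os.PathLike) -> list["SNPRecord"]:
    """Read the emap dialect back into SNPRecords (af unknown -> NaN)."""
    from .calling import SNPRecord, iupac_bases

    records: list[SNPRecord] = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields[0] != "chrom":
                    raise ValueError(f"{path}: line {lineno}: missing emap header")
                header_seen = True
                continue
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 fields")
            chrom, pos, ref, alt_call, depth, chd = fields
            chd_val = float(chd)
            if not 0.0 <= chd_val <= 1.0:
                raise ValueError(f"{path}: line {lineno}: chd {chd_val} outside [0, 1]")
            if alt_call in "ACGT":
                alt_base = alt_call
            else:
                pair = iupac_bases(alt_call)
                nonref = sorted(pair - {ref})
                if not nonref:
                    raise ValueError(f"{path}: line {lineno}: alt call {alt_call} has no non-reference base")
                alt_base = nonref[0]
            records.append(
                SNPRecord(chrom, int(pos), ref, alt_call, alt_base, int(depth),
                          chd_val, UNDEFINED)
            )
    if not header_seen:
        raise ValueError(f"{path}: no emap header line found")
    return records
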