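"""Minimal base-count SNP caller.

A deliberately simple threshold caller over pileup base counts, standing in
for heavyweight read-level pipelines: a variant is emitted when depth and the
top non-reference base clear count/fraction thresholds, and the call is a
discrete base when near-homozygous, otherwise the IUPAC two-base ambiguity
code of reference and alternate (the heterozygous-like convention, e.g. C/T
-> Y). No base qualities or genotype likelihoods are modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .mapping import allele_frequency, discordant_chastity
from .seqsim import BASES, SiteCounts

logger = logging.getLogger(__name__)

__all__ = ["CallerThresholds", "SNPRecord", "call_snps", "iupac_code", "iupac_bases"]

_IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_IUPAC_REV = {code: pair for pair, code in _IUPAC.items()}


def iupac_code(base_pair) -> str:
    """Two-base IUPAC ambiguity code (e.g. {C, T} -> 'Y')."""
    pair = frozenset(base_pair)
    if len(pair) != 2:
        raise ValueError(f"need two distinct bases, got {sorted(base_pair)}")
    if pair not in _IUPAC:
        raise ValueError(f"not a DNA base pair: {sorted(pair)}")
    return _IUPAC[pair]


def iupac_bases(code: str) -> frozenset:
    """The base pair behind a two-base IUPAC code ('Y' -> {C, T})."""
    if code not in _IUPAC_REV:
        raise ValueError(f"not a two-base IUPAC code: {code!r}")
    return _IUPAC_REV[code]


@dataclass
class CallerThresholds:
    """Count/fraction thresholds for emitting a variant record.

    ``homozygous_fraction`` is the alt fraction at or above which the call is
    reported as a discrete base; below it an IUPAC code of {ref, alt} is used.
    """

    min_depth: int = 10
    min_alt_count: int = 3
    min_alt_fraction: float = 0.15
    homozygous_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_alt_fraction < self.homozygous_fraction <= 1.0:
            raise ValueError("need 0 <= min_alt_fraction < homozygous_fraction <= 1")
        if self.min_depth < 1 or self.min_alt_count < 0:
            raise ValueError("min_depth must be >= 1 and min_alt_count >= 0")


@dataclass
class SNPRecord:
    """A called variant with its mapping statistics.

    ``alt_base`` is always the discrete most frequent non-reference base;
    ``alt_call`` is either that base or the IUPAC {ref, alt} ambiguity code.
    """

    chrom: str
    pos: int
    ref: str
    alt_call: str
    alt_base: str
    depth: int
    chd: float
    af: float

    def __post_init__(self) -> None:
        if self.alt_base == self.ref:
            raise ValueError(f"alt_base equals ref at {self.chrom}:{self.pos}")


def call_snps(sites: list[SiteCounts], thresholds: CallerThresholds | None = None) -> list[SNPRecord]:
    """Call SNPs from pileup base counts; sites failing the filters are
    silently dropped (counted in the module log).

    Ties between two non-reference bases at equal count break by fixed base
    order A<C<G<T and are logged.
    """
    thr = thresholds or CallerThresholds()
    records: list[SNPRecord] = []
    n_dropped = n_skipped_ref = 0
    for site in sites:
        if site.ref not in BASES:
            n_skipped_ref += 1
            continue
        depth = site.depth
        if depth < thr.min_depth:
            n_dropped += 1
            continue
        nonref = [(site.counts[b], b) for b in BASES if b != site.ref]
        top = max(n for n, _ in nonref)
        winners = [b for n, b in nonref if n == top]
        if len(winners) > 1 and top > 0:
            logger.info("tie at %s:%d between %s; keeping %s",
                        site.chrom, site.pos, winners, winners[0])
        alt = winners[0]  # base-order tie-break: A < C < G < T
        frac = top / depth
        if top < thr.min_alt_count or frac < thr.min_alt_fraction:
            n_dropped += 1
            continue
        alt_call = alt if frac >= thr.homozygous_fraction else iupac_code({site.ref, alt})
        records.append(
            SNPRecord(
                chrom=site.chrom, pos=site.pos, ref=site.ref,
                alt_call=alt_call, alt_base=alt, depth=depth,
                chd=discordant_chastity(site, site.ref),
                af=allele_frequency(site, alt),
            )
        )
    if n_dropped or n_skipped_ref:
        logger.info("call_snps: %d sites below thresholds, %d non-ACGT-reference sites skipped",
                    n_dropped, n_skipped_ref)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records
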