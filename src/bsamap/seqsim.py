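"""Shotgun-pool sequencing simulator at the per-site base-count level.

Reads are never materialized: at each variant site the read depth is
Poisson(mean coverage), each read's true allele is drawn from the pool allele
frequency, and a uniform substitution error (rate ``e`` per base, to any of
the other three bases) is applied. This is the count-level abstraction the
mapping statistics consume; base qualities, alignment artifacts and indels
are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .cross import Mutation, MutationSet, PoolAlleleFreqs

__all__ = [
    "SequencingParams",
    "SiteCounts",
    "simulate_site",
    "simulate_pool_pileup",
    "simulate_parent_pileup",
    "write_pileup_tsv",
    "read_pileup_tsv",
]

BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SequencingParams:
    """Mean per-site coverage (default 50x) and per-base substitution error."""

    mean_coverage: float = 50.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if not 0.0 <= self.error_rate < 0.75:
            raise ValueError("error_rate must be in [0, 0.75)")


@dataclass
class SiteCounts:
    """Observed base counts at one reference position (the pileup abstraction)."""

    chrom: str
    pos: int
    ref: str
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})

    def __post_init__(self) -> None:
        full = {b: 0 for b in BASES}
        for b, n in self.counts.items():
            if b not in _BASE_IDX:
                raise ValueError(f"bad base {b!r} in counts")
            if n < 0:
                raise ValueError(f"negative count at {self.chrom}:{self.pos}")
            full[b] = int(n)
        self.counts = full

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[b] for b in BASES], dtype=np.int64)


def _observe(true_base_counts: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply the substitution-error channel to per-true-base read counts."""
    observed = np.zeros(4, dtype=np.int64)
    for i in range(4):
        n = int(true_base_counts[i])
        if n == 0:
            continue
        if error_rate == 0.0:
            observed[i] += n
            continue
        n_err = rng.binomial(n, error_rate)
        observed[i] += n - n_err
        if n_err:
            others = [j for j in range(4) if j != i]
            spread = rng.multinomial(n_err, [1 / 3] * 3)
            for j, k in zip(others, spread):
                observed[j] += int(k)
    return observed


def simulate_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    freq: float,
    params: SequencingParams,
    rng: np.random.Generator,
) -> SiteCounts:
    """Base counts at one site with alt-allele population frequency ``freq``."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    depth = int(rng.poisson(params.mean_coverage))
    true_counts = np.zeros(4, dtype=np.int64)
    if depth:
        n_alt = int(rng.binomial(depth, freq))
        true_counts[_BASE_IDX[alt]] += n_alt
        true_counts[_BASE_IDX[ref]] += depth - n_alt
    observed = _observe(true_counts, params.error_rate, rng)
    return SiteCounts(chrom, pos, ref, {b: int(observed[i]) for i, b in enumerate(BASES)})


def simulate_pool_pileup(
    mutations: MutationSet,
    pool_freqs: PoolAlleleFreqs,
    params: SequencingParams,
    rng: np.random.Generator,
    extra_homozygous: list[Mutation] | None = None,
) -> list[SiteCounts]:
    """Pool pileup at every mutation site (plus optional fixed alt-homozygous
    sites, e.g. parental strain-vs-reference variants carried by the whole pool).

    Depth-0 sites are retained with all-zero counts; callers must skip them.
    """
    sites = [
        simulate_site(m.chrom, m.pos, m.ref, m.alt, pool_freqs.frequency(m.chrom, m.pos), params, rng)
        for m in mutations
    ]
    for v in extra_homozygous or []:
        sites.append(simulate_site(v.chrom, v.pos, v.ref, v.alt, 1.0, params, rng))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def simulate_parent_pileup(
    parent_variants: list[Mutation],
    params: SequencingParams,
    rng: np.random.Generator,
    query_sites: list[tuple[str, int, str]] | None = None,
) -> list[SiteCounts]:
    """Parent-sample pileup: homozygous alt at parent-vs-reference variant
    sites, homozygous ref at every other queried site.

    ``query_sites`` are extra ``(chrom, pos, ref)`` triples to emit (typically
    the pool's mutation positions, which the parent does not carry).
    """
    variant_at = {(v.chrom, v.pos): v for v in parent_variants}
    sites = [
        simulate_site(v.chrom, v.pos, v.ref, v.alt, 1.0, params, rng)
        for v in parent_variants
    ]
    for chrom, pos, ref in query_sites or []:
        if (chrom, pos) in variant_at:
            continue
        alt = "A" if ref != "A" else "C"  # placeholder; frequency 0 => never drawn
        sites.append(simulate_site(chrom, pos, ref, alt, 0.0, params, rng))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def write_pileup_tsv(
    sites: list[SiteCounts], path: str | os.PathLike, meta: dict | None = None
) -> None:
    """Write the pileup TSV dialect: ``chrom pos ref A C G T`` (1-based pos)
    with ``# key=value`` provenance header lines."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("chrom\tpos\tref\tA\tC\tG\tT\n")
        for s in sites:
            c = s.counts
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{c['A']}\t{c['C']}\t{c['G']}\t{c['T']}\n")


def read_pileup_tsv(path: str | os.PathLike) -> tuple[list[SiteCounts], dict[str, str]]:
    """Read the pileup TSV dialect; returns (sites, header metadata)."""
    meta: dict[str, str] = {}
    sites: list[SiteCounts] = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields[:3] != ["chrom", "pos", "ref"]:
                    raise ValueError(f"{path}: line {lineno}: missing pileup header")
                header_seen = True
                continue
            if len(fields) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 fields, got {len(fields)}")
            chrom, pos, ref = fields[0], fields[1], fields[2]
            try:
                counts = {b: int(fields[3 + i]) for i, b in enumerate(BASES)}
                site = SiteCounts(chrom, int(pos), ref, counts)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            sites.append(site)
    if not header_seen:
        raise ValueError(f"{path}: no pileup header line found")
    return sites, meta
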