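"""EMS mutagenesis, backcross/F2 meiosis, phenotypic selection and pooling.

The simulated design is a single parental backcross: a mutagenized line
(homozygous for every EMS-induced SNP, one of which is causal and recessive)
is crossed to its own non-mutagenized parent, the uniformly heterozygous F1 is
selfed, and phenotypically mutant F2 individuals — homozygous for the causal
allele, up to mis-scoring — are pooled. Because the only segregating markers
are the EMS SNPs themselves, a marker's expected pool allele frequency is
1 - r, with r the recombination fraction to the causal locus.

Chromosomes are encoded as parent-of-origin mosaics: a starting origin label
(M = mutagenized parent, P = parent) plus sorted breakpoint positions where
the origin flips. Crossovers per meiosis are Poisson with mean equal to the
chromosome's genetic length in Morgans (no interference), placed uniformly in
genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import ReferenceGenome, GeneModel

__all__ = [
    "Mutation",
    "MutationSet",
    "GeneticMap",
    "Haplotype",
    "DiploidGenotype",
    "SelectionParams",
    "PoolAlleleFreqs",
    "apply_ems",
    "designate_causal",
    "simulate_meiosis",
    "f1_diploid",
    "simulate_backcross_f2",
    "pool_allele_frequencies",
    "select_mutant_pool",
    "unlinked_marker_frequency_check",
    "haldane_r",
    "haldane_d",
    "EMS_SPECTRUM",
]

#: default EMS mutational spectrum: G:C -> A:T transitions only
EMS_SPECTRUM: dict[str, str] = {"G": "A", "C": "T"}


def haldane_r(d_morgans: float) -> float:
    """Recombination fraction for a genetic distance (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def haldane_d(r: float) -> float:
    """Genetic distance (Morgans) giving recombination fraction ``r`` < 0.5."""
    if not 0 <= r < 0.5:
        raise ValueError("r must be in [0, 0.5)")
    return -0.5 * np.log(1.0 - 2.0 * r)


@dataclass(frozen=True)
class Mutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    is_causal: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")


@dataclass
class MutationSet:
    """Sorted, position-unique set of induced mutations; at most one causal."""

    mutations: list[Mutation]

    def __post_init__(self) -> None:
        self.mutations = sorted(self.mutations, key=lambda m: (m.chrom, m.pos))
        seen = set()
        for m in self.mutations:
            key = (m.chrom, m.pos)
            if key in seen:
                raise ValueError(f"duplicate mutation position {key}")
            seen.add(key)
        if sum(m.is_causal for m in self.mutations) > 1:
            raise ValueError("more than one causal mutation")

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def __getitem__(self, i):
        return self.mutations[i]

    @property
    def causal(self) -> Mutation:
        for m in self.mutations:
            if m.is_causal:
                return m
        raise ValueError("no causal mutation designated")

    @property
    def has_causal(self) -> bool:
        return any(m.is_causal for m in self.mutations)

    def validate_against(self, genome: ReferenceGenome) -> None:
        for m in self.mutations:
            if genome.base(m.chrom, m.pos) != m.ref:
                raise ValueError(
                    f"ref mismatch at {m.chrom}:{m.pos}: genome has "
                    f"{genome.base(m.chrom, m.pos)}, mutation says {m.ref}"
                )


@dataclass
class GeneticMap:
    """Piecewise-linear physical <-> genetic position map per chromosome.

    Each chromosome stores ascending physical anchors (bp, 1-based) and the
    genetic position (Morgans) at each anchor; positions in between are
    linearly interpolated. A uniform map has two anchors.
    """

    phys: dict[str, np.ndarray]
    gen: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for c in self.phys:
            p, g = np.asarray(self.phys[c], float), np.asarray(self.gen[c], float)
            if len(p) != len(g) or len(p) < 2:
                raise ValueError(f"{c}: need matching anchor arrays of length >= 2")
            if np.any(np.diff(p) <= 0) or np.any(np.diff(g) < 0):
                raise ValueError(f"{c}: anchors must be increasing (genetic non-decreasing)")
            self.phys[c], self.gen[c] = p, g

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], morgans: float | dict[str, float]) -> "GeneticMap":
        phys, gen = {}, {}
        for c, L in chrom_lengths.items():
            m = morgans[c] if isinstance(morgans, dict) else morgans
            if m < 0:
                raise ValueError("map length must be >= 0")
            phys[c] = np.array([1.0, float(L)])
            gen[c] = np.array([0.0, float(m)])
        return cls(phys, gen, dict(chrom_lengths))

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def length_morgans(self, chrom: str) -> float:
        return float(self.gen[chrom][-1])

    def to_genetic(self, chrom: str, pos) -> np.ndarray | float:
        return np.interp(pos, self.phys[chrom], self.gen[chrom])

    def to_physical(self, chrom: str, g) -> np.ndarray:
        p = np.interp(g, self.gen[chrom], self.phys[chrom])
        return np.clip(np.rint(p).astype(np.int64), 1, self.chrom_lengths[chrom])

    def distance(self, chrom: str, pos1: int, pos2: int) -> float:
        """Genetic distance in Morgans between two positions on one chromosome."""
        return abs(float(self.to_genetic(chrom, pos1)) - float(self.to_genetic(chrom, pos2)))

    def scaled(self, factor: float) -> "GeneticMap":
        """Map with all genetic lengths multiplied by ``factor`` (recombination dial)."""
        return GeneticMap(
            {c: p.copy() for c, p in self.phys.items()},
            {c: g * factor for c, g in self.gen.items()},
            dict(self.chrom_lengths),
        )


_EMPTY = np.empty(0, dtype=np.int64)


@dataclass
class Haplotype:
    """Parent-of-origin mosaic: per chromosome, a starting label and flip points.

    ``origins[c] = (start_is_mutant, breakpoints)``; positions >= a breakpoint
    have flipped origin (once per breakpoint).
    """

    origins: dict[str, tuple[bool, np.ndarray]]

    @classmethod
    def pure(cls, chroms: list[str], mutant: bool) -> "Haplotype":
        return cls({c: (mutant, _EMPTY) for c in chroms})

    def is_mutant_at(self, chrom: str, pos) -> np.ndarray | bool:
        start, bps = self.origins[chrom]
        flips = np.searchsorted(bps, pos, side="right")
        out = (flips % 2 == 1) ^ start
        return bool(out) if np.isscalar(pos) else out


@dataclass
class DiploidGenotype:
    hap1: Haplotype
    hap2: Haplotype

    def mutant_dosage(self, chrom: str, pos: int) -> int:
        """Number of mutant-origin chromosomes (0, 1 or 2) at a position."""
        return int(self.hap1.is_mutant_at(chrom, pos)) + int(
            self.hap2.is_mutant_at(chrom, pos)
        )


@dataclass
class SelectionParams:
    pool_size: int = 110
    misscore_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0.0 <= self.misscore_rate <= 1.0:
            raise ValueError("misscore_rate must be in [0, 1]")


@dataclass
class PoolAlleleFreqs:
    """Mutant-allele frequency over the pool's 2n chromosomes, per mutation."""

    mutations: MutationSet
    freqs: np.ndarray
    n_individuals: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        if len(self.freqs) != len(self.mutations):
            raise ValueError("freqs and mutations length mismatch")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("allele frequencies must be in [0, 1]")
        self._by_site = {
            (m.chrom, m.pos): f for m, f in zip(self.mutations, self.freqs)
        }

    def frequency(self, chrom: str, pos: int) -> float:
        return self._by_site[(chrom, pos)]

    @property
    def causal_frequency(self) -> float:
        c = self.mutations.causal
        return self.frequency(c.chrom, c.pos)


# --- mutagenesis -----------------------------------------------------------

def apply_ems(
    genome: ReferenceGenome,
    gene_models: list[GeneModel],
    n_mutations: int,
    spectrum: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> MutationSet:
    """Sample EMS-induced SNPs uniformly over eligible reference sites.

    Under the default spectrum every mutation is a G->A or C->T transition.
    No causal mutation is designated here; see :func:`designate_causal`.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1 (a causal must be designatable)")
    spectrum = EMS_SPECTRUM if spectrum is None else spectrum
    rng = np.random.default_rng() if rng is None else rng
    eligible: list[tuple[str, np.ndarray, str]] = []
    total = 0
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for ref in sorted(spectrum):
            pos = np.flatnonzero(arr == ref.encode()) + 1  # 1-based
            eligible.append((chrom, pos, ref))
            total += len(pos)
    if n_mutations > total:
        raise ValueError(f"{n_mutations} mutations requested but only {total} eligible sites")
    picks = np.sort(rng.choice(total, size=n_mutations, replace=False))
    muts: list[Mutation] = []
    offset = 0
    for chrom, pos, ref in eligible:
        sel = picks[(picks >= offset) & (picks < offset + len(pos))] - offset
        for p in pos[sel]:
            muts.append(Mutation(chrom, int(p), ref, spectrum[ref]))
        offset += len(pos)
    return MutationSet(muts)


def designate_causal(
    mutations: MutationSet,
    gene_models: list[GeneModel],
    genome: ReferenceGenome,
    mode: str = "nonsense_in_CDS",
    *,
    position: tuple[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> MutationSet:
    """Flag exactly one mutation as causal.

    ``nonsense_in_CDS`` picks a CDS mutation whose codon change creates a stop
    (a recessive loss-of-function allele); ``random_genic`` any mutation inside
    a gene span; ``fixed_position`` the mutation at ``position``.
    """
    from .annotate import GeneIndex, annotate_snp  # deferred: avoids import cycle

    if mode not in {"nonsense_in_CDS", "random_genic", "fixed_position"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    candidates: list[int] = []
    if mode == "fixed_position":
        if position is None:
            raise ValueError("fixed_position mode requires position=(chrom, pos)")
        for i, m in enumerate(mutations):
            if (m.chrom, m.pos) == tuple(position):
                candidates.append(i)
        if not candidates:
            raise ValueError(f"no mutation at position {position}")
    else:
        index = GeneIndex(gene_models)
        for i, m in enumerate(mutations):
            ann = annotate_snp(m.chrom, m.pos, m.alt, index, genome)
            if mode == "random_genic" and ann.region != "intergenic":
                candidates.append(i)
            elif mode == "nonsense_in_CDS" and ann.effect == "stop-gain":
                candidates.append(i)
        if not candidates:
            raise ValueError(f"no mutation satisfies mode {mode!r}")
    chosen = candidates[int(rng.integers(len(candidates)))]
    new = [
        replace(m, is_causal=(i == chosen)) for i, m in enumerate(mutations)
    ]
    return MutationSet(new)


# --- meiosis and crossing --------------------------------------------------

def _gamete_chrom(
    hapA: tuple[bool, np.ndarray],
    hapB: tuple[bool, np.ndarray],
    xovers: np.ndarray,
    start_with_a: bool,
) -> tuple[bool, np.ndarray]:
    """Compose one gamete chromosome from two parental mosaics and crossovers."""
    # collapse coincident crossovers (even multiplicity cancels)
    if len(xovers):
        uniq, counts = np.unique(xovers, return_counts=True)
        xovers = uniq[counts % 2 == 1]
    a_start, a_bps = hapA
    b_start, b_bps = hapB
    if len(a_bps) == 0 and len(b_bps) == 0:
        # fast path: pure parental chromosomes (always the case for an F1)
        first = a_start if start_with_a else b_start
        if a_start == b_start:
            return first, _EMPTY
        return first, xovers.astype(np.int64)
    # general path: evaluate origin just after every candidate flip point
    points = np.union1d(np.union1d(a_bps, b_bps), xovers).astype(np.int64)
    probe = np.concatenate(([np.int64(0)], points))  # origin on [prev, next)
    from_a = (np.searchsorted(xovers, probe, side="right") % 2 == 0) == start_with_a
    a_val = ((np.searchsorted(a_bps, probe, side="right") % 2 == 1) ^ a_start)
    b_val = ((np.searchsorted(b_bps, probe, side="right") % 2 == 1) ^ b_start)
    origin = np.where(from_a, a_val, b_val)
    flips = points[origin[1:] != origin[:-1]]
    return bool(origin[0]), flips


def simulate_meiosis(
    diploid: DiploidGenotype, genetic_map: GeneticMap, rng: np.random.Generator
) -> Haplotype:
    """One gamete: Poisson(map length) crossovers per chromosome, uniform in
    genetic distance, starting haplotype chosen with probability 1/2."""
    origins: dict[str, tuple[bool, np.ndarray]] = {}
    for chrom in genetic_map.chroms:
        L = genetic_map.length_morgans(chrom)
        k = int(rng.poisson(L)) if L > 0 else 0
        if k:
            g = rng.uniform(0.0, L, size=k)
            xovers = np.sort(genetic_map.to_physical(chrom, g))
        else:
            xovers = _EMPTY
        start_with_a = bool(rng.integers(2) == 0)
        origins[chrom] = _gamete_chrom(
            diploid.hap1.origins[chrom], diploid.hap2.origins[chrom], xovers, start_with_a
        )
    return Haplotype(origins)


def f1_diploid(chroms: list[str]) -> DiploidGenotype:
    """The backcross F1: one full mutant-origin and one full parent-origin set."""
    return DiploidGenotype(Haplotype.pure(chroms, True), Haplotype.pure(chroms, False))


def simulate_backcross_f2(
    mutation_set: MutationSet,
    genetic_map: GeneticMap,
    n_f2: int,
    rng: np.random.Generator,
) -> list[DiploidGenotype]:
    """Self the backcross F1: each F2 is two independent meioses of the F1."""
    if n_f2 < 1:
        raise ValueError("n_f2 must be >= 1")
    f1 = f1_diploid(genetic_map.chroms)
    return [
        DiploidGenotype(
            simulate_meiosis(f1, genetic_map, rng),
            simulate_meiosis(f1, genetic_map, rng),
        )
        for _ in range(n_f2)
    ]


def pool_allele_frequencies(
    pool: list[DiploidGenotype], mutations: MutationSet
) -> PoolAlleleFreqs:
    """Mutant-origin chromosome fraction at every mutation site, from haplotypes."""
    by_chrom: dict[str, list[int]] = {}
    idx: dict[str, list[int]] = {}
    for i, m in enumerate(mutations):
        by_chrom.setdefault(m.chrom, []).append(m.pos)
        idx.setdefault(m.chrom, []).append(i)
    freqs = np.zeros(len(mutations))
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions)
        counts = np.zeros(len(pos))
        for ind in pool:
            counts += ind.hap1.is_mutant_at(chrom, pos)
            counts += ind.hap2.is_mutant_at(chrom, pos)
        freqs[idx[chrom]] = counts / (2 * len(pool))
    return PoolAlleleFreqs(mutations, freqs, len(pool))


def select_mutant_pool(
    population: list[DiploidGenotype],
    mutations: MutationSet,
    selection: SelectionParams,
    rng: np.random.Generator,
) -> tuple[list[DiploidGenotype], PoolAlleleFreqs]:
    """Phenotypic selection of homozygous-mutant F2s, with optional mis-scoring.

    Each selected individual is, with probability ``misscore_rate``, replaced
    by a phenotypically wild-type segregant (drawn from the non-homozygous F2,
    whose genotypes are PP:MP at the Mendelian 1:2 conditional ratio).
    """
    causal = mutations.causal
    mutant_idx = [
        i for i, ind in enumerate(population)
        if ind.mutant_dosage(causal.chrom, causal.pos) == 2
    ]
    other_idx = [i for i in range(len(population)) if i not in set(mutant_idx)]
    n = selection.pool_size
    if len(mutant_idx) < n:
        raise ValueError(
            f"population has {len(mutant_idx)} homozygous mutants, need {n}"
        )
    chosen = rng.choice(len(mutant_idx), size=n, replace=False)
    pool = [population[mutant_idx[i]] for i in chosen]
    if selection.misscore_rate > 0:
        if not other_idx:
            raise ValueError("mis-scoring requested but no wild-type segregants exist")
        flips = rng.random(n) < selection.misscore_rate
        for j in np.flatnonzero(flips):
            pool[j] = population[other_idx[int(rng.integers(len(other_idx)))]]
    return pool, pool_allele_frequencies(pool, mutations)


def unlinked_marker_frequency_check(freqs: PoolAlleleFreqs) -> dict[str, float | int]:
    """Mean pool frequency of markers on chromosomes without the causal locus
    (expectation 0.5 — a sanity check on selection and meiosis)."""
    causal_chrom = freqs.mutations.causal.chrom
    mask = np.array([m.chrom != causal_chrom for m in freqs.mutations])
    n = int(mask.sum())
    mean = float(freqs.freqs[mask].mean()) if n else float("nan")
    return {"n_markers": n, "mean_frequency": mean, "expected": 0.5}
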