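"""End-to-end pipeline: simulation runs, mapping runs, and the resolution
experiment sweeping pool size x coverage x mis-scoring x recombination.

Every command is deterministic under a fixed seed; each output file carries a
provenance header recording the seed and parameters it was produced with.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross, seqsim
from .annotate import GeneIndex, annotate_records, write_annotation_tsv
from .calling import CallerThresholds, call_snps
from .cross import GeneticMap, Mutation, MutationSet, SelectionParams
from .genome import generate_toy_genome, read_fasta, read_gff3, write_fasta, write_gff3
from .mapping import (
    CandidateReport,
    MappingConfig,
    filter_genic,
    filter_parental,
    rank_candidates,
    threshold_candidates,
    write_emap,
)
from .seqsim import SequencingParams, read_pileup_tsv, write_pileup_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_map", "resolution_experiment"]


@dataclass
class RunConfig:
    """All tunables of a simulated screen-and-map run.

    Defaults are the study conditions: ~500 EMS SNPs, a 110-individual mutant
    pool drawn from a segregating F2 population, ~50x coverage, on a
    scaled-down 5 x 1 Mb genome with Arabidopsis-like per-chromosome genetic
    lengths (1.2 Morgans) and ~12% of the genome inside gene spans.
    """

    seed: int = 0
    # toy genome
    n_chrom: int = 5
    chrom_length: int = 1_000_000
    n_genes: int = 250
    # genetic map (uniform; Morgans per chromosome)
    morgans_per_chrom: float = 1.2
    map_scale: float = 1.0
    # mutagenesis and cross
    n_ems_snps: int = 500
    n_parent_variants: int = 150
    n_f2: int = 600
    causal_mode: str = "nonsense_in_CDS"
    selection: SelectionParams = field(default_factory=SelectionParams)
    sequencing: SequencingParams = field(default_factory=SequencingParams)
    caller: CallerThresholds = field(default_factory=CallerThresholds)
    mapping: MappingConfig = field(default_factory=MappingConfig)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("selection", SelectionParams),
            ("sequencing", SequencingParams),
            ("caller", CallerThresholds),
            ("mapping", MappingConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        flat = {}
        for k, v in d.items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    flat[f"{k}.{kk}"] = vv
            else:
                flat[k] = v
        return flat

    def genetic_map(self, chrom_lengths: dict[str, int]) -> GeneticMap:
        gmap = GeneticMap.uniform(chrom_lengths, self.morgans_per_chrom)
        if self.map_scale != 1.0:
            gmap = gmap.scaled(self.map_scale)
        return gmap


@dataclass
class SimulationResult:
    genome: object
    gene_models: list
    genetic_map: GeneticMap
    mutations: MutationSet
    parent_variants: list[Mutation]
    pool_freqs: cross.PoolAlleleFreqs
    parent_sites: list
    pool_sites: list


def _sample_parent_variants(genome, mutations: MutationSet, n: int, rng) -> list[Mutation]:
    """Strain-vs-reference differences carried homozygously by parent, F1 and
    every F2 (any substitution, not EMS-restricted); avoid EMS positions."""
    taken = {(m.chrom, m.pos) for m in mutations}
    chroms = list(genome.chromosomes)
    lengths = genome.lengths
    variants: list[Mutation] = []
    while len(variants) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, lengths[chrom] + 1))
        if (chrom, pos) in taken:
            continue
        ref = genome.base(chrom, pos)
        if ref not in "ACGT":
            continue
        alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
        variants.append(Mutation(chrom, pos, ref, alt))
        taken.add((chrom, pos))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def simulate_screen(config: RunConfig, rng: np.random.Generator | None = None) -> SimulationResult:
    """Run the whole generative model in memory (no files).

    Mutagenesis is re-drawn (up to 50 attempts) until the mutation set
    contains a designatable causal under ``causal_mode`` — the screen, by
    construction, recovered a mutant, so a causal allele must exist.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genome, models = generate_toy_genome(
        config.n_chrom, config.chrom_length, config.n_genes, rng
    )
    mutations = None
    for _ in range(50):
        candidate_set = cross.apply_ems(genome, models, config.n_ems_snps, rng=rng)
        try:
            mutations = cross.designate_causal(
                candidate_set, models, genome, config.causal_mode, rng=rng
            )
            break
        except ValueError:
            continue
    if mutations is None:
        raise RuntimeError(
            f"no {config.causal_mode} causal could be designated in 50 mutagenesis draws"
        )
    gmap = config.genetic_map(genome.lengths)
    population = cross.simulate_backcross_f2(mutations, gmap, config.n_f2, rng)
    pool, freqs = cross.select_mutant_pool(population, mutations, config.selection, rng)
    parent_variants = _sample_parent_variants(genome, mutations, config.n_parent_variants, rng)

    query = [(m.chrom, m.pos, m.ref) for m in mutations]
    parent_sites = seqsim.simulate_parent_pileup(
        parent_variants, config.sequencing, rng, query_sites=query
    )
    # the whole pool is homozygous for the parental strain variants (freq 1)
    pool_sites = seqsim.simulate_pool_pileup(
        mutations, freqs, config.sequencing, rng, extra_homozygous=parent_variants
    )
    return SimulationResult(
        genome, models, gmap, mutations, parent_variants, freqs, parent_sites, pool_sites
    )


def run_simulate(config: RunConfig, outdir: str | os.PathLike) -> dict[str, Path]:
    """Simulate a screen and write genome FASTA, GFF3, parent and pool pileups
    and the ground-truth table. Deterministic for a fixed seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_screen(config)
    meta = config.provenance()

    paths = {
        "fasta": out / "genome.fasta",
        "gff3": out / "genes.gff3",
        "parent_pileup": out / "parent.pileup.tsv",
        "pool_pileup": out / "pool.pileup.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    write_fasta(sim.genome, paths["fasta"])
    write_gff3(sim.gene_models, paths["gff3"])
    write_pileup_tsv(sim.parent_sites, paths["parent_pileup"], meta={"sample": "parent", **meta})
    write_pileup_tsv(sim.pool_sites, paths["pool_pileup"], meta={"sample": "pool", **meta})
    with open(paths["truth"], "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("chrom\tpos\tref\talt\tis_causal\ttrue_pool_frequency\n")
        for m, f in zip(sim.mutations, sim.pool_freqs.freqs):
            fh.write(f"{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\t{int(m.is_causal)}\t{f!r}\n")
    config.to_yaml(paths["config"])
    return paths


@dataclass
class MapResult:
    report: CandidateReport
    stage_counts: dict[str, int]
    records: list
    annotations: dict


def _check_chrom_names(pool_sites, parent_sites, gene_models) -> None:
    pool_chroms = {s.chrom for s in pool_sites}
    gff_chroms = {m.chrom for m in gene_models}
    parent_chroms = {s.chrom for s in parent_sites}
    if gene_models and not (pool_chroms & gff_chroms):
        raise ValueError(
            f"chromosome-name mismatch: pool pileup has {sorted(pool_chroms)}, "
            f"gene models have {sorted(gff_chroms)}"
        )
    if parent_sites and not (pool_chroms & parent_chroms):
        raise ValueError(
            f"chromosome-name mismatch: pool pileup has {sorted(pool_chroms)}, "
            f"parent pileup has {sorted(parent_chroms)}"
        )


def map_candidates(
    pool_sites,
    parent_sites,
    gene_models,
    genome,
    config: RunConfig,
) -> MapResult:
    """call -> parental filter -> (optional) genic filter -> threshold ->
    annotate -> rank, with per-stage record counts."""
    _check_chrom_names(pool_sites, parent_sites, gene_models)
    mcfg = config.mapping
    pool_records = call_snps(pool_sites, config.caller)
    parent_records = call_snps(parent_sites, config.caller)
    stage = {"called_pool": len(pool_records), "called_parent": len(parent_records)}
    records = filter_parental(pool_records, parent_records, mcfg.parent_match_mode)
    stage["after_parental_filter"] = len(records)
    index = GeneIndex(gene_models)
    if mcfg.genic_only:
        records = filter_genic(records, index)
    stage["after_genic_filter"] = len(records)
    candidates = threshold_candidates(records, mcfg.chd_threshold)
    stage["after_chd_threshold"] = len(candidates)
    annotations = annotate_records(candidates, index, genome)
    report = rank_candidates(candidates, annotations, mcfg.chd_threshold)
    logger.info("mapping stage counts: %s", stage)
    return MapResult(report, stage, candidates, annotations)


def run_map(
    parent_pileup: str | os.PathLike,
    pool_pileup: str | os.PathLike,
    gff3: str | os.PathLike,
    fasta: str | os.PathLike,
    config: RunConfig,
    outdir: str | os.PathLike,
) -> MapResult:
    """File-level mapping run: reads pileups/GFF3/FASTA, writes the emap file,
    candidate report and stage counts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pool_sites, pool_meta = read_pileup_tsv(pool_pileup)
    parent_sites, _ = read_pileup_tsv(parent_pileup)
    gene_models = read_gff3(gff3)
    genome = read_fasta(fasta)
    result = map_candidates(pool_sites, parent_sites, gene_models, genome, config)

    meta = {"seed": config.seed, **{f"pool.{k}": v for k, v in pool_meta.items()}}
    all_records = call_snps(pool_sites, config.caller)
    parent_records = call_snps(parent_sites, config.caller)
    emap_records = filter_parental(all_records, parent_records, config.mapping.parent_match_mode)
    write_emap(emap_records, out / "pool.emap.tsv", meta=meta)
    write_annotation_tsv(
        [r for r, _, _ in result.report.entries],
        result.annotations,
        out / "candidates.tsv",
        decimals=config.mapping.report_decimals,
    )
    with open(out / "stage_counts.tsv", "w") as fh:
        fh.write("stage\tcount\n")
        for k, v in result.stage_counts.items():
            fh.write(f"{k}\t{v}\n")
    return result


def resolution_experiment(
    grid: list[dict],
    n_replicates: int,
    seed: int,
    base_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Sweep (pool size, coverage, mis-scoring, recombination scale) cells.

    Per cell, over replicates: the fraction where the causal SNP is the unique
    top-ranked candidate, the mean rank of the causal, and the mean number of
    candidates tied at the maximum Ch_D.
    """
    base = base_config or RunConfig()
    rows = []
    cell_rng = np.random.default_rng(seed)
    for cell in grid:
        seeds = cell_rng.integers(0, 2**31 - 1, size=n_replicates)
        n_unique_top = 0
        ranks, co_top = [], []
        for s in seeds:
            cfg = dataclasses.replace(
                base,
                seed=int(s),
                selection=SelectionParams(
                    pool_size=int(cell.get("pool_size", base.selection.pool_size)),
                    misscore_rate=float(cell.get("misscore_rate", base.selection.misscore_rate)),
                ),
                sequencing=SequencingParams(
                    mean_coverage=float(cell.get("coverage", base.sequencing.mean_coverage)),
                    error_rate=base.sequencing.error_rate,
                ),
                map_scale=float(cell.get("map_scale", base.map_scale)),
            )
            cfg = dataclasses.replace(
                cfg, n_f2=max(cfg.n_f2, int(cfg.selection.pool_size / 0.25 * 1.35) + 20)
            )
            sim = simulate_screen(cfg)
            res = map_candidates(sim.pool_sites, sim.parent_sites, sim.gene_models, sim.genome, cfg)
            causal = sim.mutations.causal
            rank = next(
                (k for r, _, k in res.report.entries
                 if (r.chrom, r.pos) == (causal.chrom, causal.pos)),
                None,
            )
            ranks.append(rank if rank is not None else np.nan)
            if res.report.entries:
                max_chd = max(r.chd for r, _, _ in res.report.entries)
                n_top = sum(1 for r, _, _ in res.report.entries if r.chd == max_chd)
            else:
                n_top = 0
            co_top.append(n_top)
            if rank == 1 and n_top == 1:
                n_unique_top += 1
        rows.append({
            **cell,
            "n_replicates": n_replicates,
            "frac_unique_top": n_unique_top / n_replicates,
            "mean_rank_causal": float(np.nanmean(ranks)) if ranks else np.nan,
            "mean_n_top_chd": float(np.mean(co_top)),
        })
    return pd.DataFrame(rows)
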