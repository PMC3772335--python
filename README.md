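# bsamap

Simulation and analysis toolkit for mapping-by-sequencing of recessive
EMS-induced mutations via a single-backcross bulked-segregant design.

## The method

An EMS-mutagenized line carrying a recessive phenotype of interest is crossed
once to its non-mutagenized parent strain. The F1 is selfed, and homozygous
mutant F2 segregants (expected at 1/4 under Mendelian segregation) are pooled
and sequenced, together with the parent strain. Because every pooled
individual is homozygous at the causal locus, the causal mutation — and
tightly linked EMS markers — approach an alternate-allele frequency of 1 in
the pool, while unlinked markers segregate at ~0.5.

Linkage is scored per site with the **discordant chastity** statistic

```
Ch_D = N(top non-reference base) / (N(most common base) + N(second most common base))
```

computed from pooled base counts. `Ch_D` is 1 exactly when only a single
non-reference base is observed, 0 when no non-reference base is observed, and
coincides with the alternate-allele frequency at biallelic sites. Candidates
are obtained by removing variants shared with the parent strain, restricting
to genic sites, thresholding at `Ch_D ≥ 0.85`, annotating codon effects
(strand-aware; heterozygous IUPAC calls yield an ambiguous codon with a blank
amino-acid column), and ranking by `Ch_D` with effect severity breaking ties —
a nonsense (stop-gain) change outranks missense at equal chastity.

The package provides:

- a toy-genome and gene-model generator (FASTA / GFF3 in and out),
- an EMS mutagenesis and backcross/F2 meiosis simulator (Poisson crossovers
  on a genetic map, no interference, optional phenotype mis-scoring),
- a pooled-pileup sequencing simulator (Poisson coverage, per-base error),
- a count-based SNP caller with IUPAC heterozygous calls,
- the mapping core (Ch_D, parental and genic filters, thresholding, ranking),
- codon-effect annotation, and
- a `bsamap` command-line interface tying these together.

## Worked example

```python
from bsamap.pipeline import RunConfig, simulate_screen, map_candidates

cfg = RunConfig(seed=0)                 # 5 x 1 Mb genome, 500 EMS SNPs,
sim = simulate_screen(cfg)              # 110-segregant pool, 50x coverage
res = map_candidates(sim.pool_sites, sim.parent_sites,
                     sim.gene_models, sim.genome, cfg)
print(res.stage_counts)
best = res.report.best
print(best.chrom, best.pos, best.chd)   # the causal stop-gain, Ch_D = 1.0
```

Or from the shell:

```
bsamap simulate --seed 0 --outdir scratch/run0
bsamap map --parent scratch/run0/parent.pileup.tsv \
           --pool scratch/run0/pool.pileup.tsv \
           --gff3 scratch/run0/genes.gff3 \
           --fasta scratch/run0/genome.fasta \
           --outdir scratch/run0/mapped
```

`mapped/candidates.tsv` lists ranked candidates with codon annotations;
`mapped/pool.emap.tsv` holds per-site calls with `Ch_D`.

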