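# Methods

## Experimental design being modeled

A recessive mutant recovered from an EMS screen is backcrossed once to the
non-mutagenized parent strain. The F1 (heterozygous for every induced
mutation) is selfed. F2 individuals segregate 1 homozygous mutant : 2
heterozygous : 1 homozygous wild-type at the causal locus; the visible
phenotype therefore segregates 1 mutant : 3 wild-type. Homozygous mutant F2
segregants are pooled and the pool is sequenced alongside the parent strain.

Selection fixes the mutant allele at the causal locus in the pool. Markers at
recombination fraction `r` from the causal locus reach an expected pooled
mutant-allele frequency of `1 − r` (each selected chromosome carries the
linked marker unless a crossover separated them), decaying to 0.5 for
unlinked markers. Scanning pooled allele frequencies therefore localizes the
causal interval without pre-existing marker maps.

## Genetic model

- **Mutagenesis.** EMS produces G:C→A:T transitions; `apply_ems` draws
  mutation positions uniformly from G/C reference sites. One induced mutation
  is designated causal; the default mode requires it to be a nonsense
  (stop-gain) change inside a CDS, re-drawing the mutation set if none
  qualifies.
- **Meiosis.** Crossovers per chromosome are Poisson with mean equal to the
  chromosome's genetic length in Morgans, placed uniformly in genetic
  distance and mapped to physical coordinates through a piecewise-linear
  genetic map. No crossover interference. This reproduces the Haldane mapping
  function `r = (1 − e^{−2d})/2` exactly; `haldane_r`/`haldane_d` are
  provided and verified against simulation.
- **Haplotypes** are stored as parent-of-origin mosaics: a starting label and
  a sorted breakpoint list per chromosome. Allele lookup is a binary-search
  parity test, so populations of 10^5 F2 individuals simulate in seconds.
- **Selection and mis-scoring.** The pool takes `pool_size` individuals
  homozygous at the causal locus. With mis-scoring rate `ε`, each pool slot
  is replaced with probability `ε` by a random non-homozygous F2 individual
  (het or wild-type), diluting the pooled mutant-allele frequency; at `ε = 1`
  the causal frequency tends to 1/3 (the het:wt ratio among non-mutants is
  2:1 and hets contribute half their alleles).

## Sequencing model

Per site, read depth is Poisson(`mean_coverage`); each read reports the true
sampled allele with probability `1 − e` and otherwise one of the three other
bases uniformly. Homozygous parent-strain variants (present in both parent
and pool, since the whole pedigree is homozygous for them) are simulated at
frequency 1 in both pileups; they are exactly what the parental filter
removes. Pileups are exchanged as TSV (`chrom pos ref A C G T`) with a
`# key=value` provenance header.

## Calling and mapping

- **Caller.** At each site with depth ≥ `min_depth`, the most frequent
  non-reference base (ties broken A<C<G<T, logged) becomes the alternate if
  it meets `min_alt_count` and `min_alt_fraction`. If its fraction of the
  depth is below `homozygous_fraction` (0.9), the call is the IUPAC
  ambiguity code of {ref, alt}; otherwise the discrete base.
- **Discordant chastity.**
  `Ch_D = N(top non-ref) / (N(1st) + N(2nd most common base))`. It is 0 when
  no non-reference base is observed, 1 iff the top base is non-reference and
  the second-most-common count is zero, NaN at depth 0 (NaN never passes a
  threshold), and equals the alternate-allele frequency at biallelic sites.
- **Filters.** Parental filtering removes calls shared with the parent
  (by position, or position+allele). Genic filtering keeps sites within
  annotated gene spans (UTRs and introns included) via an interval tree.
  Candidates require `Ch_D ≥ 0.85`.
- **Annotation.** CDS sites are translated strand-aware: on the minus strand
  the alternate base is complemented (ambiguity codes complement code-wise,
  e.g. Y↔R) before substitution into the coding codon. Codons containing an
  ambiguity code are classified `ambiguous` and the derived amino acid is
  left blank (e.g. `P →`), even when both readings are synonymous — the
  convention is lexical, not biochemical.
- **Ranking.** Candidates sort by descending `Ch_D`, then effect severity
  (stop-gain > stop-loss > missense > synonymous/ambiguous > noncoding),
  then coordinate. Tightly linked markers can genuinely tie at `Ch_D = 1`
  (zero recombinants in a finite pool); severity is what separates the
  causal nonsense change in that case.

## Default study conditions and rationale

| Parameter | Default | Rationale |
|---|---|---|
| Genome | 5 chromosomes × 1 Mb | small enough for fast simulation, several chromosomes so most markers are unlinked |
| Genetic length | 1.2 M/chromosome | plant-like cM/Mb density; ample recombination across 1 Mb |
| Genes | 250 (~2.35 kb each) | ~12% genic fraction, so roughly one in eight induced SNPs lands in a gene |
| EMS SNPs | 500 | typical induced load for a single mutagenized line |
| Parent variants | 150 | background shared variants exercised by the parental filter |
| F2 population | 600 | ≥110 homozygotes available with probability ≈ 1 − 8×10⁻⁵ |
| Pool size | 110 | homozygous segregants pooled |
| Coverage | 50× Poisson | pooled-resequencing depth |
| Error rate | 0.001 | per-base sequencing error |
| Ch_D threshold | 0.85 | separates the linked cluster from unlinked markers at this pool size and depth |

These were fixed from the experimental design before any end-to-end runs;
none were tuned against outcomes.

## Numerical conventions

- All randomness flows through explicit `numpy.random.Generator` objects;
  file outputs are byte-identical across runs at the same seed.
- 1-based, fully closed genomic coordinates throughout.
- `Ch_D` is serialized at full precision in `.emap.tsv`; report TSVs round
  for display only.
- Caller tie-breaks and region assignment for overlapping genes are
  deterministic (lexicographic) and logged.

## Limitations

- Reads are independent per-base draws: no mapping bias, indels, paired-end
  structure, duplicated regions, or quality scores.
- No crossover interference and a uniform default genetic map.
- EMS spectrum is pure G:C→A:T; real screens show a small fraction of other
  changes.
- The caller is count-based and diploid-pool-specific; it is not a general
  genotype-likelihood caller.
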