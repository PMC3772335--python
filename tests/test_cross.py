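import numpy as np
import pytest

from bsamap.cross import (
    EMS_SPECTRUM,
    GeneticMap,
    Mutation,
    MutationSet,
    SelectionParams,
    apply_ems,
    designate_causal,
    f1_diploid,
    haldane_d,
    haldane_r,
    pool_allele_frequencies,
    select_mutant_pool,
    simulate_backcross_f2,
    simulate_meiosis,
    unlinked_marker_frequency_check,
)
from bsamap.genome import ReferenceGenome


def one_chrom_map(length=1_000_000, morgans=1.2, name="c"):
    return GeneticMap.uniform({name: length}, morgans)


class TestApplyEms:
    def test_default_spectrum_is_gc_to_at(self, toy, rng):
        genome, models = toy
        ms = apply_ems(genome, models, 200, rng=rng)
        assert len(ms) == 200
        assert all((m.ref, m.alt) in {("G", "A"), ("C", "T")} for m in ms)
        ms.validate_against(genome)

    def test_zero_mutations_rejected(self, toy, rng):
        genome, models = toy
        with pytest.raises(ValueError):
            apply_ems(genome, models, 0, rng=rng)

    def test_deterministic_for_fixed_seed(self, toy):
        genome, models = toy
        a = apply_ems(genome, models, 50, rng=np.random.default_rng(5))
        b = apply_ems(genome, models, 50, rng=np.random.default_rng(5))
        assert a.mutations == b.mutations

    def test_too_many_mutations(self):
        genome = ReferenceGenome({"c": "ATGC" * 10})
        with pytest.raises(ValueError, match="eligible"):
            apply_ems(genome, [], 1000, rng=np.random.default_rng(0))


class TestDesignateCausal:
    def test_nonsense_mode_picks_stop_gain(self, toy, rng):
        genome, models = toy
        for attempt in range(30):
            ms = apply_ems(genome, models, 300, rng=rng)
            try:
                out = designate_causal(ms, models, genome, "nonsense_in_CDS", rng=rng)
                break
            except ValueError:
                continue
        else:
            pytest.fail("no stop-gain found in 30 draws")
        causal = out.causal
        from bsamap.annotate import GeneIndex, annotate_snp
        ann = annotate_snp(causal.chrom, causal.pos, causal.alt, GeneIndex(models), genome)
        assert ann.effect == "stop-gain"

    def test_fixed_position_absent_raises(self, toy, rng):
        genome, models = toy
        ms = apply_ems(genome, models, 10, rng=rng)
        with pytest.raises(ValueError, match="no mutation at position"):
            designate_causal(ms, models, genome, "fixed_position", position=("chr1", 1))

    def test_random_genic_forced_choice(self, toy, rng):
        genome, models = toy
        model = models[0]
        pos = model.cds[0][0]
        ref = genome.base(model.chrom, pos)
        alt = "A" if ref != "A" else "T"
        genic = Mutation(model.chrom, pos, ref, alt)
        intergenic = Mutation(model.chrom, 1, genome.base(model.chrom, 1),
                              "C" if genome.base(model.chrom, 1) != "C" else "G")
        ms = MutationSet([genic, intergenic])
        out = designate_causal(ms, models, genome, "random_genic", rng=rng)
        assert out.causal.pos == pos

    def test_exactly_one_causal(self, toy, rng):
        genome, models = toy
        ms = apply_ems(genome, models, 100, rng=rng)
        out = designate_causal(ms, models, genome, "random_genic", rng=rng)
        assert sum(m.is_causal for m in out) == 1


class TestMeiosis:
    def test_zero_map_length_gives_pure_parental_gamete(self, rng):
        gmap = one_chrom_map(morgans=0.0)
        f1 = f1_diploid(["c"])
        for _ in range(20):
            g = simulate_meiosis(f1, gmap, rng)
            start, bps = g.origins["c"]
            assert len(bps) == 0

    def test_deterministic_for_fixed_seed(self):
        gmap = one_chrom_map()
        f1 = f1_diploid(["c"])
        a = simulate_meiosis(f1, gmap, np.random.default_rng(9))
        b = simulate_meiosis(f1, gmap, np.random.default_rng(9))
        assert a.origins["c"][0] == b.origins["c"][0]
        assert np.array_equal(a.origins["c"][1], b.origins["c"][1])

    def test_recombination_fraction_matches_binomial_oracle(self):
        # two loci at Haldane distance for r = 0.1; recombinant-gamete
        # fraction over 100,000 meioses within 3 binomial SE of r
        r = 0.1
        d = haldane_d(r)
        gmap = one_chrom_map(morgans=1.2)
        pos_a = 100_000
        pos_b = int(pos_a + d / 1.2 * 999_999)
        f1 = f1_diploid(["c"])
        rng = np.random.default_rng(3)
        n = 100_000
        rec = 0
        for _ in range(n):
            g = simulate_meiosis(f1, gmap, rng)
            rec += g.is_mutant_at("c", pos_a) != g.is_mutant_at("c", pos_b)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(rec / n - r) < 3 * se

    def test_haldane_round_trip(self):
        for r in (0.01, 0.1, 0.3, 0.49):
            assert haldane_r(haldane_d(r)) == pytest.approx(r)


class TestBackcrossF2:
    def test_segregation_one_to_three(self):
        gmap = one_chrom_map()
        ms = MutationSet([Mutation("c", 500_000, "G", "A", True)])
        rng = np.random.default_rng(4)
        n = 20_000
        pop = simulate_backcross_f2(ms, gmap, n, rng)
        n_mut = sum(ind.mutant_dosage("c", 500_000) == 2 for ind in pop)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(n_mut / n - 0.25) < 3 * se

    def test_genotype_one_two_one(self):
        # MM:MP:PP expected 1:2:1 at the causal locus (chi-square over 20k F2)
        from scipy import stats
        gmap = one_chrom_map()
        ms = MutationSet([Mutation("c", 500_000, "G", "A", True)])
        pop = simulate_backcross_f2(ms, gmap, 20_000, np.random.default_rng(8))
        dosages = [ind.mutant_dosage("c", 500_000) for ind in pop]
        obs = [dosages.count(2), dosages.count(1), dosages.count(0)]
        stat, p = stats.chisquare(obs, f_exp=[5000, 10_000, 5000])
        assert p > 1e-4

    def test_zero_map_gives_full_parental_haplotypes(self, rng):
        gmap = one_chrom_map(morgans=0.0)
        ms = MutationSet([Mutation("c", 10, "G", "A", True)])
        pop = simulate_backcross_f2(ms, gmap, 50, rng)
        for ind in pop:
            for hap in (ind.hap1, ind.hap2):
                assert len(hap.origins["c"][1]) == 0

    def test_population_size_validated(self, rng):
        ms = MutationSet([Mutation("c", 10, "G", "A", True)])
        with pytest.raises(ValueError):
            simulate_backcross_f2(ms, one_chrom_map(), 0, rng)

    def test_origin_labels_total_one_per_haplotype(self, rng):
        # conservation: exactly one origin per haplotype position
        gmap = one_chrom_map()
        ms = MutationSet([Mutation("c", 500_000, "G", "A", True)])
        pop = simulate_backcross_f2(ms, gmap, 20, rng)
        pos = np.array([1, 250_000, 500_000, 999_999])
        for ind in pop:
            for hap in (ind.hap1, ind.hap2):
                vals = hap.is_mutant_at("c", pos)
                assert vals.dtype == bool and vals.shape == pos.shape


class TestSelection:
    def _setup(self, extra_markers=(), morgans=1.2, n_f2=600, seed=0):
        gmap = one_chrom_map(morgans=morgans)
        muts = [Mutation("c", 500_000, "G", "A", True)]
        muts += [Mutation("c", p, "C", "T") for p in extra_markers]
        ms = MutationSet(muts)
        rng = np.random.default_rng(seed)
        pop = simulate_backcross_f2(ms, gmap, n_f2, rng)
        return ms, pop, rng

    def test_perfect_selection_causal_frequency_exactly_one(self):
        for seed in range(5):
            ms, pop, rng = self._setup(seed=seed)
            _, freqs = select_mutant_pool(pop, ms, SelectionParams(110, 0.0), rng)
            assert freqs.causal_frequency == 1.0

    def test_linked_marker_frequency_one_minus_r(self):
        # E[pool frequency] = 1 - r for a marker at recombination fraction r;
        # conditional-gamete oracle: each causal-carrying gamete carries the
        # marker with probability 1 - r, so the pooled count is binomial
        r = 0.1
        d = haldane_d(r)
        marker = int(500_000 + d / 1.2 * 999_999)
        total, n_chrom = 0.0, 0
        reps = 25
        for seed in range(reps):
            ms, pop, rng = self._setup((marker,), seed=100 + seed)
            _, freqs = select_mutant_pool(pop, ms, SelectionParams(110, 0.0), rng)
            total += freqs.frequency("c", marker)
            n_chrom += 220
        se = np.sqrt(r * (1 - r) / n_chrom)
        assert abs(total / reps - (1 - r)) < 3 * se

    def test_fully_linked_marker_frequency_one(self):
        ms, pop, rng = self._setup((500_001,), morgans=0.0)
        _, freqs = select_mutant_pool(pop, ms, SelectionParams(110, 0.0), rng)
        assert freqs.frequency("c", 500_001) == 1.0

    def test_single_misscored_heterozygote_dilutes_causal(self):
        # one heterozygote among 110 -> causal frequency 219/220 < 1
        ms, pop, rng = self._setup()
        pool, freqs = select_mutant_pool(pop, ms, SelectionParams(110, 0.0), rng)
        het = next(ind for ind in pop if ind.mutant_dosage("c", 500_000) == 1)
        pool[0] = het
        diluted = pool_allele_frequencies(pool, ms)
        assert diluted.causal_frequency == pytest.approx(219 / 220)

    def test_full_misscoring_gives_one_third(self):
        # epsilon = 1: pool is all phenotypic wild-type (PP:MP at 1:2), so the
        # causal allele frequency approaches 1/3 (Mendelian arithmetic oracle)
        totals = []
        for seed in range(10):
            ms, pop, rng = self._setup(seed=200 + seed)
            _, freqs = select_mutant_pool(pop, ms, SelectionParams(110, 1.0), rng)
            totals.append(freqs.causal_frequency)
        # each pooled individual contributes 0 or 1 mutant alleles of 2;
        # var of the mean over 1100 draws is small
        assert abs(np.mean(totals) - 1 / 3) < 0.03

    def test_unlinked_marker_mean_half(self):
        gmap = GeneticMap.uniform({"c1": 500_000, "c2": 500_000}, 1.0)
        muts = [Mutation("c1", 250_000, "G", "A", True)]
        muts += [Mutation("c2", p, "C", "T") for p in range(50_000, 500_000, 50_000)]
        ms = MutationSet(muts)
        rng = np.random.default_rng(17)
        pop = simulate_backcross_f2(ms, gmap, 600, rng)
        _, freqs = select_mutant_pool(pop, ms, SelectionParams(110, 0.0), rng)
        summary = unlinked_marker_frequency_check(freqs)
        assert summary["n_markers"] == 9
        assert abs(summary["mean_frequency"] - 0.5) < 0.1

    def test_insufficient_mutants_raises(self):
        ms, pop, rng = self._setup(n_f2=40)
        with pytest.raises(ValueError, match="homozygous mutants"):
            select_mutant_pool(pop, ms, SelectionParams(110, 0.0), rng)

    def test_misscore_rate_validated(self):
        with pytest.raises(ValueError):
            SelectionParams(110, 1.5)


class TestGeneticMap:
    def test_piecewise_monotone_required(self):
        with pytest.raises(ValueError):
            GeneticMap({"c": np.array([1, 100, 50])},
                       {"c": np.array([0.0, 0.5, 1.0])}, {"c": 100})

    def test_scaled(self):
        gmap = one_chrom_map(morgans=1.0).scaled(0.5)
        assert gmap.length_morgans("c") == 0.5

    def test_physical_genetic_round_trip_uniform(self):
        gmap = one_chrom_map(length=1000, morgans=2.0)
        g = gmap.to_genetic("c", 500)
        assert gmap.to_physical("c", g) == 500
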