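"""Ground-truth generators: diploid genomes, planted SSRs, k-mer histograms,
structured genotype tables."""

import numpy as np
import pytest

from pistasurvey import simulate, ssr
from pistasurvey.diversity import NULL
from pistasurvey.simulate import GenomeSimSpec, PlantedSSR, PopSimSpec


class TestDiploidGenome:
    def test_zero_rate_identity(self):
        h1, h2, het = simulate.simulate_diploid_genome(GenomeSimSpec(10_000, het_rate=0.0, seed=1))
        assert h1 == h2 and het.size == 0

    def test_gc_content_within_binomial_noise(self):
        spec = GenomeSimSpec(1_000_000, gc_content=0.5, het_rate=0.0, seed=2)
        h1, _, _ = simulate.simulate_diploid_genome(spec)
        gc = sum(h1.count(b) for b in "GC") / len(h1)
        assert abs(gc - 0.5) <= 3 * np.sqrt(0.25 / 1e6)

    def test_het_fraction_within_binomial_noise(self):
        spec = GenomeSimSpec(1_000_000, het_rate=0.01, seed=3)
        h1, h2, het = simulate.simulate_diploid_genome(spec)
        frac = het.size / 1e6
        assert abs(frac - 0.01) <= 3 * np.sqrt(0.01 * 0.99 / 1e6)
        # truth positions are exactly the differing positions (1-based)
        diffs = np.flatnonzero(np.frombuffer(h1.encode(), np.uint8)
                               != np.frombuffer(h2.encode(), np.uint8)) + 1
        assert np.array_equal(het, diffs)

    def test_reproducible(self):
        spec = GenomeSimSpec(5_000, seed=4)
        assert simulate.simulate_diploid_genome(spec)[0] == simulate.simulate_diploid_genome(spec)[0]

    def test_short_genome_warns(self):
        with pytest.warns(UserWarning):
            simulate.simulate_diploid_genome(GenomeSimSpec(20, seed=0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSimSpec(0)
        with pytest.raises(ValueError):
            GenomeSimSpec(10, gc_content=1.5)


class TestPlantedSSRs:
    def test_dinucleotide_recovered_exactly(self):
        h1, h2, _ = simulate.simulate_diploid_genome(GenomeSimSpec(1_000, het_rate=0.0, seed=5))
        (haps, truth) = simulate.plant_ssrs((h1, h2), [PlantedSSR(100, "AT", 6)], seed=6)
        loci = ssr.scan_perfect_ssrs(haps[0])
        match = [l for l in loci if l.start == 100]
        assert len(match) == 1
        assert (match[0].end, match[0].motif, match[0].n_repeats) == (111, "AT", 6)

    def test_trinucleotide_length(self):
        h1, h2, _ = simulate.simulate_diploid_genome(GenomeSimSpec(1_000, het_rate=0.0, seed=7))
        (haps, truth) = simulate.plant_ssrs((h1, h2), [PlantedSSR(200, "AAG", 5)], seed=8)
        (t,) = truth
        assert t.end - t.start + 1 == 15
        found = [l for l in ssr.scan_perfect_ssrs(haps[0]) if l.start == 200]
        assert found and found[0].motif == "AAG" and found[0].n_repeats == 5

    def test_overlapping_insertions_error(self):
        h1, h2, _ = simulate.simulate_diploid_genome(GenomeSimSpec(1_000, seed=9))
        with pytest.raises(ValueError, match="overlap"):
            simulate.plant_ssrs((h1, h2), [PlantedSSR(100, "AT", 6), PlantedSSR(105, "AAG", 5)])

    def test_fifty_planted_in_1mb_full_recall(self):
        spec = GenomeSimSpec(1_000_000, gc_content=0.371, het_rate=0.01, seed=10)
        h1, h2, _ = simulate.simulate_diploid_genome(spec)
        planted = simulate.random_planted_ssrs(50, 1_000_000, seed=11)
        (haps, truth) = simulate.plant_ssrs((h1, h2), planted, seed=12)
        found = {(l.start, l.end, l.motif, l.n_repeats) for l in ssr.scan_perfect_ssrs(haps[0])}
        truth_set = {(t.start, t.end, t.motif, t.n_repeats) for t in truth}
        assert len(truth_set) == 50
        assert truth_set <= found  # recall 100%

    def test_below_threshold_motif_rejected(self):
        with pytest.raises(ValueError):
            PlantedSSR(1, "AT", 5)
        with pytest.raises(ValueError):
            PlantedSSR(1, "ATAT", 4)  # non-primitive motif


class TestKmerHistogramSim:
    def test_unimodal_mode_near_coverage(self):
        h1, h2, _ = simulate.simulate_diploid_genome(GenomeSimSpec(200_000, het_rate=0.0, seed=13))
        hist = simulate.simulate_kmer_histogram((h1, h2), coverage=25, k=17, seed=14)
        mode = hist.depths[int(np.argmax(hist.counts))]
        assert abs(mode - 25) <= 2

    def test_half_depth_mass_grows_with_het(self):
        masses = []
        for h in (0.0, 0.005, 0.01, 0.02):
            h1, h2, _ = simulate.simulate_diploid_genome(
                GenomeSimSpec(200_000, het_rate=h, seed=15)
            )
            hist = simulate.simulate_kmer_histogram((h1, h2), coverage=30, k=17, seed=16)
            sel = (hist.depths >= 8) & (hist.depths <= 22)  # around coverage/2
            masses.append(hist.counts[sel].sum())
        assert masses == sorted(masses) and masses[-1] > masses[0]

    def test_empty_genome_empty_histogram(self):
        hist = simulate.simulate_kmer_histogram(("", ""), coverage=30, k=17)
        assert hist.depths.size == 0

    def test_k_longer_than_sequence_errors(self):
        with pytest.raises(ValueError):
            simulate.simulate_kmer_histogram(("ACGTACGT", "ACGTACGT"), coverage=30, k=17)

    def test_mass_conservation_and_reproducibility(self):
        h1, h2, _ = simulate.simulate_diploid_genome(GenomeSimSpec(50_000, seed=17))
        a = simulate.simulate_kmer_histogram((h1, h2), coverage=20, k=17, seed=18)
        b = simulate.simulate_kmer_histogram((h1, h2), coverage=20, k=17, seed=18)
        assert np.array_equal(a.depths, b.depths) and np.array_equal(a.counts, b.counts)
        # mass identity: sum depth*count equals the total occurrences emitted
        assert a.total_kmers == (a.depths * a.counts).sum()

    def test_error_kmers_pile_at_depth_one(self):
        h1, h2, _ = simulate.simulate_diploid_genome(GenomeSimSpec(50_000, het_rate=0.0, seed=19))
        clean = simulate.simulate_kmer_histogram((h1, h2), coverage=30, k=17, seed=20)
        noisy = simulate.simulate_kmer_histogram(
            (h1, h2), coverage=30, k=17, error_rate=0.002, seed=20
        )
        c1 = clean.counts[clean.depths == 1].sum()
        n1 = noisy.counts[noisy.depths == 1].sum()
        assert n1 > c1 + 10_000  # ~ error_rate*k*cov*L = 51k new singletons


class TestGenotypeTables:
    def test_alleles_on_grid(self):
        spec = PopSimSpec(n_pops=2, n_per_pop=10, n_loci=20, fst=0.2, seed=21)
        table, _ = simulate.simulate_genotype_table(spec)
        grid = set(spec.allele_size_grid)
        typed = table.a1 >= 0
        assert set(table.a1[typed].tolist()) <= grid
        assert set(table.a2[typed].tolist()) <= grid

    def test_membership_one_hot_and_null_consistency(self):
        spec = PopSimSpec(
            n_pops=3, n_per_pop=(4, 5, 6), n_loci=30, fst=0.2,
            null_locus_rate=(0.0, 0.2, 0.4), seed=22,
        )
        table, truth = simulate.simulate_genotype_table(spec)
        assert np.array_equal(truth["membership"].sum(axis=1), np.ones(15))
        table.validate_null_consistency()
        # null truth matches the table
        for p, sp in enumerate(["sp1", "sp2", "sp3"]):
            rows = table.species_rows(sp)
            isnull = np.all(table.a1[rows] == NULL, axis=0)
            assert np.array_equal(isnull, truth["null"][p])

    def test_degenerate_fst_rejected(self):
        for f in (0.0, 1.0):
            with pytest.raises(ValueError):
                PopSimSpec(n_pops=2, n_per_pop=5, n_loci=5, fst=f)

    def test_low_fst_populations_nearly_identical(self):
        spec = PopSimSpec(n_pops=2, n_per_pop=5, n_loci=50, fst=1e-4, seed=23)
        _, truth = simulate.simulate_genotype_table(spec)
        diff = np.abs(truth["pop_freqs"][0] - truth["pop_freqs"][1]).max()
        assert diff < 0.05

    def test_reproducible(self):
        spec = PopSimSpec(n_pops=2, n_per_pop=5, n_loci=10, fst=0.2, seed=24)
        t1, _ = simulate.simulate_genotype_table(spec)
        t2, _ = simulate.simulate_genotype_table(spec)
        assert np.array_equal(t1.a1, t2.a1) and np.array_equal(t1.a2, t2.a2)
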