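"""Allele frequencies, per-locus statistics, transferability, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pistasurvey import datasets, diversity
from pistasurvey.diversity import MISSING, NULL, GenotypeTable


class TestAlleleFreqs:
    def test_direct_count(self, small_table):
        # species A at L1: calls (100,100),(100,120) -> p(100)=0.75
        f = diversity.allele_freqs(small_table, "L1", [0, 1])
        assert f == {100: 0.75, 120: 0.25}

    def test_single_homozygote(self, small_table):
        f = diversity.allele_freqs(small_table, "L1", [0])
        assert f == {100: 1.0}

    def test_unamplified_errors(self, small_table):
        with pytest.raises(ValueError, match="not amplified"):
            diversity.allele_freqs(small_table, "L3", [2, 3])

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        n = 50
        sizes = rng.choice([100, 102, 104, 106], size=(n, 2))
        t = GenotypeTable(
            [f"i{j}" for j in range(n)], ["s"] * n, ["L1"], sizes[:, :1], sizes[:, 1:]
        )
        f = diversity.allele_freqs(t, "L1")
        tally = {}
        for v in sizes.ravel():
            tally[v] = tally.get(v, 0) + 1
        assert f == {a: c / (2 * n) for a, c in sorted(tally.items())}


class TestLocusStats:
    def test_even_biallelic(self):
        # p = (.5, .5): Ne 2, He .5, PIC .375
        a = np.array([[100], [120]])
        b = np.array([[120], [100]])
        t = GenotypeTable(["x", "y"], ["s", "s"], ["L"], a, b)
        s = diversity.locus_stats(t, "L")
        assert s.na == 2 and s.ne == pytest.approx(2.0)
        assert s.he == pytest.approx(0.5) and s.pic == pytest.approx(0.375)
        assert s.ho == 1.0

    def test_monomorphic(self):
        t = GenotypeTable(["x", "y"], ["s", "s"], ["L"], [[100], [100]], [[100], [100]])
        s = diversity.locus_stats(t, "L")
        assert (s.na, s.ne, s.ho, s.he, s.pic) == (1, 1.0, 0.0, 0.0, 0.0)

    def test_three_allele_hand_values(self):
        # p = (.5, .25, .25): He = .625, Ne = 2.667 (3 s.f.)
        a1 = np.array([[100], [100], [104], [106]])
        a2 = np.array([[100], [100], [104], [106]])
        t = GenotypeTable(list("wxyz"), ["s"] * 4, ["L"], a1, a2)
        s = diversity.locus_stats(t, "L")
        assert s.he == pytest.approx(0.625)
        assert s.ne == pytest.approx(2.667, abs=5e-4)

    def test_missing_excluded_from_ho_denominator(self, small_table):
        s = diversity.locus_stats(small_table, "L2")
        assert s.n_typed == 3  # b2 missing
        assert s.ho == pytest.approx(2 / 3)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8).map(
            lambda w: np.array(w) / np.sum(w)
        )
    )
    def test_invariants_on_random_frequencies(self, p):
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        he = 1 - s2
        pic = 1 - s2 - (s2**2 - s4)
        ne = 1 / s2
        assert 0 <= pic <= he + 1e-12 <= 1
        assert 1 - 1e-12 <= ne <= len(p) + 1e-12
        assert he <= (len(p) - 1) / len(p) + 1e-12

    def test_he_pic_invariant_under_relabeling(self):
        a1 = np.array([[100], [104], [100]])
        a2 = np.array([[104], [108], [108]])
        t1 = GenotypeTable(list("abc"), ["s"] * 3, ["L"], a1, a2)
        t2 = GenotypeTable(list("abc"), ["s"] * 3, ["L"], a1 + 100, a2 + 100)
        s1, s2 = diversity.locus_stats(t1, "L"), diversity.locus_stats(t2, "L")
        assert s1.he == s2.he and s1.pic == s2.pic and s1.ne == s2.ne


class TestTransferability:
    @pytest.mark.parametrize(
        "n_amp,expect", [(151, 73.3), (177, 85.9), (200, 97.1), (206, 100.0), (0, 0.0)]
    )
    def test_worked_ratios(self, n_amp, expect):
        # one individual per species; 206 loci, n_amp amplified in species B
        n_loci = 206
        a = np.full((2, n_loci), 100)
        b = np.full((2, n_loci), 100)
        a[1, n_amp:] = NULL
        b[1, n_amp:] = NULL
        t = GenotypeTable(
            ["a1", "b1"], ["A", "B"], [f"L{j}" for j in range(n_loci)], a, b
        )
        assert diversity.transferability(t, "B") == expect

    def test_unknown_species_errors(self, small_table):
        with pytest.raises(KeyError):
            diversity.transferability(small_table, "Z")


def brute_force_species_summary(table, species):
    """Independent recomputation with plain dict/loop tallies."""
    rows = [i for i, s in enumerate(table.species) if s == species]
    amplified, poly_stats = [], []
    for j, locus in enumerate(table.loci):
        copies = []
        genos = []
        for i in rows:
            x, y = int(table.a1[i, j]), int(table.a2[i, j])
            if x >= 0:
                copies += [x, y]
                genos.append((x, y))
        if not copies:
            continue
        amplified.append(locus)
        freqs = {a: copies.count(a) / len(copies) for a in set(copies)}
        if len(freqs) < 2:
            continue
        s2 = sum(p * p for p in freqs.values())
        pic = 1 - s2 - sum(
            2 * freqs[a] ** 2 * freqs[b] ** 2
            for ai, a in enumerate(sorted(freqs))
            for b in sorted(freqs)[ai + 1 :]
        )
        poly_stats.append(
            dict(
                na=len(freqs),
                ne=1 / s2,
                ho=sum(x != y for x, y in genos) / len(genos),
                he=1 - s2,
                pic=pic,
            )
        )
    return amplified, poly_stats


class TestSpeciesSummary:
    def test_matches_brute_force(self):
        from pistasurvey.simulate import PopSimSpec, simulate_genotype_table

        spec = PopSimSpec(
            n_pops=3, n_per_pop=6, n_loci=15, fst=0.3,
            null_locus_rate=(0.0, 0.2, 0.4), missing_rate=0.05, seed=17,
        )
        table, _ = simulate_genotype_table(spec)
        for sp in table.species_names:
            summary = diversity.species_summary(table, sp)
            amplified, poly = brute_force_species_summary(table, sp)
            assert summary.n_amplified_loci == len(amplified)
            assert summary.n_polymorphic_loci == len(poly)
            assert summary.total_polymorphic_alleles == sum(p["na"] for p in poly)
            if poly:
                for key in ("na", "ne", "ho", "he", "pic"):
                    expect = round(float(np.mean([p[key] for p in poly])), 2)
                    assert getattr(summary, f"mean_{key}") == expect

    def test_all_monomorphic_flagged(self):
        a = np.full((3, 4), 100)
        t = GenotypeTable(list("abc"), ["s"] * 3, list("WXYZ"), a, a.copy())
        summary = diversity.species_summary(t, "s")
        assert summary.n_polymorphic_loci == 0 and summary.mean_pic is None

    def test_null_rate_quarter_transferability_near_75(self):
        from pistasurvey.simulate import PopSimSpec, simulate_genotype_table

        spec = PopSimSpec(
            n_pops=2, n_per_pop=8, n_loci=400, fst=0.2,
            null_locus_rate=(0.0, 0.25), seed=23,
        )
        table, truth = simulate_genotype_table(spec)
        t = diversity.transferability(table, "sp2")
        # binomial(400, .75): 3 sd ~ 6.5 points
        assert abs(t - 75.0) <= 6.5
        assert t == round(100.0 * (400 - truth["null"][1].sum()) / 400, 1)


class TestUniversalLoci:
    def test_null_locus_excluded(self, small_table):
        amp, poly = diversity.universal_loci(small_table)
        assert "L3" not in amp
        assert set(amp) == {"L1", "L2"}

    def test_polymorphic_in_all(self, small_table):
        amp, poly = diversity.universal_loci(small_table)
        # L1: species A has {100,120}, B has {102,104} -> polymorphic in both
        # L2: B has only one typed individual with alleles {200,204} -> still Na=2
        assert set(poly) == {"L1", "L2"}

    def test_single_species_returns_amplified(self):
        a = np.array([[100, NULL], [102, NULL]])
        t = GenotypeTable(["x", "y"], ["s", "s"], ["L1", "L2"], a, a.copy())
        amp, _ = diversity.universal_loci(t)
        assert amp == ["L1"]


class TestLocusTableSummary:
    def test_published_pistachio_table(self):
        df = datasets.load_pistacia_locus_table()
        out = diversity.summarize_locus_table(df)
        assert out["total_alleles"] == 2036
        assert out["mean_na"] == 9.88
        assert out["mean_ne"] == 4.67
        assert out["mean_ho"] == 0.41
        assert out["mean_he"] == 0.74
        assert out["mean_pic"] == 0.71

    def test_published_table_satisfies_invariants(self):
        df = datasets.load_pistacia_locus_table()
        assert len(df) == 206
        assert (df["pic"] <= df["he"] + 1e-9).all()
        assert (df["ne"] <= df["na"] + 1e-9).all()
        assert df["ho"].between(0, 1).all()
        assert (df["allele_min"] < df["allele_max"]).all()

    def test_published_table_universal_marker_counts(self):
        df = datasets.load_pistacia_locus_table()
        assert int(df["amplified_all_species"].sum()) == 136
        assert int(df["polymorphic_all_species"].sum()) == 41

    def test_two_hand_rows(self):
        df = pd.DataFrame(
            {"na": [2, 4], "ne": [1.5, 3.5], "ho": [0.2, 0.6], "he": [0.3, 0.7], "pic": [0.25, 0.65]}
        )
        out = diversity.summarize_locus_table(df)
        assert out == {
            "n_loci": 2, "total_alleles": 6, "mean_na": 3.0, "mean_ne": 2.5,
            "mean_ho": 0.4, "mean_he": 0.5, "mean_pic": 0.45,
        }


class TestCsvRoundTrip:
    def test_round_trip(self, small_table, tmp_path):
        p = tmp_path / "geno.csv"
        small_table.to_csv(p)
        t2 = GenotypeTable.from_csv(p)
        assert t2.individuals == small_table.individuals
        assert t2.species == small_table.species
        assert t2.loci == small_table.loci
        assert np.array_equal(t2.a1, small_table.a1)
        assert np.array_equal(t2.a2, small_table.a2)

    def test_null_consistency_validation(self):
        a1 = np.array([[100], [NULL]])
        t = GenotypeTable(["x", "y"], ["s", "s"], ["L"], a1, a1.copy())
        with pytest.raises(ValueError, match="inconsistent null"):
            t.validate_null_consistency()
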