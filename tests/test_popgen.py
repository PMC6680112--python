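"""Genotype filtering, SNP classification and popgen summary statistics."""

import numpy as np
import pytest

from palmspec.popgen import (
    classify_snps,
    dxy,
    filter_genotypes,
    fst,
    fu_li_star,
    mean_pairwise_differences,
    nucleotide_diversity,
    observed_heterozygosity,
    species_consensus,
    spectrum_stats,
    summarize_gene,
    tajimas_d,
)

from conftest import make_gm
from _oracles import oracle_dxy, oracle_pi_total


class TestFilter:
    def test_low_maf_site_removed(self):
        # 20 diploids, 2 alt alleles of 40 -> MAF 0.05 < 0.1
        row = [1, 1] + [0] * 18
        gm = make_gm([row, [1] * 20], ["A"] * 10 + ["B"] * 10)
        out = filter_genotypes(gm)
        assert out.n_sites == 1 and out.positions[0] == 2

    def test_low_call_rate_site_removed(self):
        # 60% called < 70% minimum call rate
        row = [1] * 6 + [-1] * 4
        gm = make_gm([row], ["A"] * 5 + ["B"] * 5)
        assert filter_genotypes(gm).n_sites == 0

    def test_quality_and_depth_blank_genotypes(self):
        gm = make_gm(
            [[1] * 10],
            ["A"] * 5 + ["B"] * 5,
            gq=np.full((1, 10), 99.0),
            dp=np.array([[2.0] * 4 + [10.0] * 6]),
        )
        out = filter_genotypes(gm, max_missing=0.5)
        # four genotypes dropped for depth; site survives at 60% call rate
        assert (out.genotypes[0, :4] == -1).all()
        assert (out.genotypes[0, 4:] == 1).all()

    def test_passing_sites_are_identity(self):
        gm = make_gm([[0, 1, 2, 1], [1, 1, 0, 2]], ["A", "A", "B", "B"])
        out = filter_genotypes(gm)
        assert np.array_equal(out.genotypes, gm.genotypes)


class TestClassification:
    def test_three_class_examples(self):
        dosages = [
            [0, 0, 2, 2],  # fixed
            [0, 1, 0, 0],  # private-A
            [1, 1, 1, 1],  # shared
        ]
        gm = make_gm(dosages, ["A", "A", "B", "B"])
        assert classify_snps(gm) == ["fixed", "private-A", "shared"]

    def test_uncallable_when_one_species_missing(self):
        gm = make_gm([[1, 1, -1, -1]], ["A", "A", "B", "B"])
        assert classify_snps(gm) == ["uncallable"]

    def test_symmetry_under_species_relabeling(self):
        dosages = [[0, 0, 2, 2], [0, 1, 0, 0], [1, 1, 1, 1], [0, 0, 1, 0]]
        gm = make_gm(dosages, ["A", "A", "B", "B"])
        flipped = make_gm(
            [row[2:] + row[:2] for row in dosages], ["A", "A", "B", "B"]
        )
        swap = {"private-A": "private-B", "private-B": "private-A"}
        want = [swap.get(c, c) for c in classify_snps(gm)]
        assert classify_snps(flipped) == want

    def test_class_counts_sum_to_sites(self, small_dataset):
        _, matrices, _ = small_dataset
        for gm in matrices[:10]:
            labels = classify_snps(gm)
            assert len(labels) == gm.n_sites


class TestDiversity:
    def test_hand_counted_example(self):
        # 4 alleles A,A,T,T at one site, L=100: pi = (2*(1/2)^2*(4/3))/100
        gm = make_gm([[1, 1]], ["A", "A"])
        assert nucleotide_diversity(gm, "A", 100) == pytest.approx(0.0066667, abs=1e-6)

    def test_monomorphic_is_zero(self):
        gm = make_gm([[2, 2, 2, 2]], ["A"] * 4)
        assert nucleotide_diversity(gm, "A", 50) == 0.0

    def test_zero_length_rejected(self):
        gm = make_gm([[1, 1]], ["A", "A"])
        with pytest.raises(ValueError):
            nucleotide_diversity(gm, "A", 0)

    def test_matches_enumerated_pair_oracle(self):
        rng = np.random.default_rng(3)
        dosages = rng.integers(0, 3, size=(12, 8))
        dosages[rng.random(dosages.shape) < 0.1] = -1
        gm = make_gm(dosages, ["A"] * 8)
        want = oracle_pi_total(dosages)
        assert mean_pairwise_differences(gm, "A") == pytest.approx(want)
        assert nucleotide_diversity(gm, "A", 200) == pytest.approx(want / 200)


class TestTajima:
    def test_worked_case_n4_s3(self):
        assert tajimas_d(3, 4, 10 / 6) == pytest.approx(0.1676557950, abs=1e-6)

    def test_zero_when_pi_matches_watterson(self):
        a1 = sum(1 / i for i in range(1, 8))
        assert tajimas_d(5, 8, 5 / a1) == pytest.approx(0.0, abs=1e-12)

    def test_negative_for_singleton_excess(self):
        # S singletons in n alleles: pi_total = S * 2/n
        n, S = 20, 40
        assert tajimas_d(S, n, S * 2 / n) < 0

    def test_undefined_for_no_segregating_sites(self):
        with pytest.raises(ValueError):
            tajimas_d(0, 10, 0.0)


class TestFuLiStar:
    def test_sign_properties(self):
        d_hi, f_hi = fu_li_star(S=10, n=10, n_singletons=0, pi_total=4.0)
        d_lo, f_lo = fu_li_star(S=10, n=10, n_singletons=10, pi_total=2.0)
        assert d_hi > 0 and d_lo < 0
        assert f_lo < f_hi

    @pytest.mark.parametrize("n,S,eta_s,pi", [(4, 3, 1, 1.5), (10, 12, 4, 3.2), (20, 30, 9, 8.0)])
    def test_against_independent_constant_sheet(self, n, S, eta_s, pi):
        # independently coded evaluation of the starred variance constants
        an = sum(1.0 / i for i in range(1, n))
        bn = sum(1.0 / i**2 for i in range(1, n))
        an1 = an + 1.0 / n
        cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
        dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
            1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
        )
        vd = (
            (n / (n - 1)) ** 2 * bn + an**2 * dn - 2 * n * an * (an + 1) / (n - 1) ** 2
        ) / (an**2 + bn)
        ud = (n / (n - 1)) * (an - n / (n - 1)) - vd
        want_d = ((n / (n - 1)) * S - an * eta_s) / (ud * S + vd * S**2) ** 0.5
        got_d, got_f = fu_li_star(S, n, eta_s, pi)
        assert got_d == pytest.approx(want_d, abs=1e-12)
        vf = (
            dn
            + 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            - 2 / (n - 1) * (4 * bn - 6 + 8.0 / n)
        ) / (an**2 + bn)
        uf = (
            n / (n - 1)
            + (n + 1) / (3 * (n - 1))
            - 4.0 / (n * (n - 1))
            + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
        ) / an - vf
        want_f = (pi - (n - 1) / n * eta_s) / (uf * S + vf * S**2) ** 0.5
        assert got_f == pytest.approx(want_f, abs=1e-12)


class TestFst:
    def test_all_fixed_differences_give_one(self):
        gm = make_gm([[0, 0, 2, 2], [2, 2, 0, 0]], ["A", "A", "B", "B"])
        assert fst(gm) == pytest.approx(1.0)

    def test_single_fixed_site(self):
        gm = make_gm([[2, 2, 0, 0]], ["A", "A", "B", "B"])
        assert fst(gm) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        # both species drawn from the same allele frequencies
        dosages = rng.binomial(2, 0.4, size=(50, 200)).astype(np.int8)
        gm = make_gm(dosages, ["A"] * 100 + ["B"] * 100)
        assert abs(fst(gm)) < 0.02

    def test_no_usable_sites_undefined(self):
        gm = make_gm([[0, 0, 0, 0]], ["A", "A", "B", "B"])
        assert fst(gm) is None


class TestDxy:
    def test_two_fixed_of_hundred_sites(self):
        gm = make_gm([[0, 0, 2, 2], [2, 2, 0, 0]], ["A", "A", "B", "B"])
        assert dxy(gm, 100) == pytest.approx(0.02)

    def test_identical_species_zero(self):
        gm = make_gm([[1, 1, 1, 1]], ["A", "A", "B", "B"])
        # p_A = p_B = 0.5 -> per-site 0.5, analytic
        assert dxy(gm, 1) == pytest.approx(0.5)
        gm2 = make_gm([[2, 2, 2, 2]], ["A", "A", "B", "B"])
        assert dxy(gm2, 10) == pytest.approx(0.0)

    def test_matches_enumerated_cross_pair_oracle(self):
        rng = np.random.default_rng(9)
        dosages = rng.integers(0, 3, size=(15, 10)).astype(np.int8)
        gm = make_gm(dosages, ["A"] * 5 + ["B"] * 5)
        want = oracle_dxy(dosages[:, :5], dosages[:, 5:], 99)
        assert dxy(gm, 99) == pytest.approx(want)


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "dosages,expected",
        [
            ([[1, 1, 1, 1]], 1.0),
            ([[0, 0, 2, 2]], 0.0),
            ([[1, 0, 1, 2], [1, 0, 1, 0]], 0.5),
        ],
    )
    def test_examples(self, dosages, expected):
        gm = make_gm(dosages, ["A"] * 4)
        assert observed_heterozygosity(gm, "A") == expected


class TestConsensus:
    def test_fixed_alt_substituted_and_tie_keeps_reference(self):
        gm = make_gm(
            [[2, 2, 0, 0], [1, 1, 0, 0]],
            ["A", "A", "B", "B"],
            positions=[2, 5],
            ref=["C", "G"],
            alt=["T", "A"],
        )
        ref_seq = "ACGTGCAAA"
        # site 1: species A fixed alt -> T; site 2: 50/50 -> keep G
        assert species_consensus(gm, ref_seq, "A") == "ATGTGCAAA"
        assert species_consensus(gm, ref_seq, "B") == ref_seq

    def test_no_snps_returns_reference(self):
        gm = make_gm(np.zeros((0, 4), dtype=np.int8), ["A", "A", "B", "B"], positions=[])
        assert species_consensus(gm, "ACGT", "A") == "ACGT"

    def test_inconsistent_reference_rejected(self):
        gm = make_gm([[2, 2, 0, 0]], ["A", "A", "B", "B"], ref=["T"])
        with pytest.raises(ValueError):
            species_consensus(gm, "AAAA", "A")


class TestSummary:
    def test_summary_consistency_on_synthetic_gene(self, small_dataset, small_params):
        _, matrices, _ = small_dataset
        gm = next(g for g in matrices if g.n_sites >= 3)
        s = summarize_gene(gm, 3 * small_params.gene_length_codons)
        assert s.n_snps == gm.n_sites
        assert sum(s.class_counts.values()) == s.n_snps
        assert s.pi_per_site["all"] >= 0
        assert s.dxy_per_site >= 0

    def test_spectrum_stats_singletons(self):
        gm = make_gm([[0, 0, 0, 1], [1, 0, 0, 0]], ["A"] * 4)
        st = spectrum_stats(gm, "A")
        assert st["S"] == 2 and st["singletons"] == 2 and st["n"] == 8
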