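"""Generator invariants: determinism, rate calibration, truth/file consistency."""

import numpy as np
import pandas as pd
import pytest

from palmspec.codons import STOP_CODONS
from palmspec.popgen import classify_snps
from palmspec.screen import ECOLOGICAL_TERMS, REPRODUCTIVE_TERMS
from palmspec.synthetic_data import (
    SimParams,
    _nb_draw,
    gen_count_matrix,
    gen_gene_alignments,
    gen_go_map,
    gen_read_pairs,
    read_vcf,
    write_vcf,
)
from palmspec.expression import rpm


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"theta_within": -0.1},
            {"frac_selected": 1.5},
            {"omega_selected": 0.0},
            {"gene_length_codons": 5},
            {"lib_size_range": (0, 10)},
            {"dup_family_size_distribution": {1: 0.5, 2: 0.4}},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs).validate()


class TestAlignments:
    def test_seeded_runs_byte_identical(self):
        p = SimParams(n_genes=20, frac_selected=0.1, seed=1)
        a1, g1, t1 = gen_gene_alignments(p)
        a2, g2, t2 = gen_gene_alignments(SimParams(n_genes=20, frac_selected=0.1, seed=1))
        for x, y in zip(a1, a2):
            assert x.sequences == y.sequences
        for x, y in zip(g1, g2):
            assert np.array_equal(x.genotypes, y.genotypes)
        assert t1.df.equals(t2.df)

    def test_no_internal_stops_in_consensus(self, small_dataset):
        aligns, _, _ = small_dataset
        for al in aligns:
            for name, seq in al.sequences.items():
                if name.endswith("_consensus"):
                    codons = {seq[i : i + 3] for i in range(0, len(seq) - 3, 3)}
                    assert not (codons & STOP_CODONS)

    def test_zero_divergence_means_no_fixed_snps(self):
        p = SimParams(n_genes=15, divergence_per_site=0.0, seed=4)
        aligns, matrices, truth = gen_gene_alignments(p)
        assert truth.df["n_fixed_nonsyn"].sum() + truth.df["n_fixed_syn"].sum() == 0
        for al in aligns:
            assert al.sequences["A_consensus"] == al.sequences["B_consensus"]

    def test_zero_theta_makes_all_snps_fixed(self):
        p = SimParams(n_genes=15, theta_within=0.0, divergence_per_site=0.01, seed=4)
        _, matrices, _ = gen_gene_alignments(p)
        labels = [c for gm in matrices for c in classify_snps(gm)]
        assert labels and set(labels) == {"fixed"}

    def test_snp_rates_converge_to_expectation(self):
        p = SimParams(
            n_genes=500, gene_length_codons=100, theta_within=0.004,
            divergence_per_site=0.003, frac_shared=0.0, seed=6,
        )
        _, matrices, truth = gen_gene_alignments(p)
        n_sites = 500 * 300
        n_fixed = int(truth.df["n_fixed_nonsyn"].sum() + truth.df["n_fixed_syn"].sum())
        expect_fixed = n_sites * p.divergence_per_site
        assert abs(n_fixed - expect_fixed) < 5 * np.sqrt(expect_fixed)
        n_poly = int(truth.df["n_poly"].sum())
        expect_poly = 2 * n_sites * p.theta_within  # two species
        assert abs(n_poly - expect_poly) < 5 * np.sqrt(expect_poly)

    def test_selected_genes_have_elevated_nonsynonymous_fraction(self):
        p = SimParams(n_genes=300, divergence_per_site=0.01, seed=2)
        _, _, truth = gen_gene_alignments(p)
        df = truth.df
        frac = lambda d: d["n_fixed_nonsyn"].sum() / max(
            1, d["n_fixed_nonsyn"].sum() + d["n_fixed_syn"].sum()
        )
        assert frac(df[df["is_selected"]]) > frac(df[~df["is_selected"]]) + 0.2

    def test_alignment_haplotypes_agree_with_genotype_matrix(self, small_dataset):
        aligns, matrices, _ = small_dataset
        for al, gm in list(zip(aligns, matrices))[:8]:
            for si, (pos, alt) in enumerate(zip(gm.positions, gm.alt)):
                for col, sample in enumerate(gm.samples):
                    d = int(gm.genotypes[si, col])
                    hap_alleles = [
                        al.sequences[f"{sample}_h1"][pos - 1],
                        al.sequences[f"{sample}_h2"][pos - 1],
                    ]
                    assert hap_alleles.count(alt) == d


class TestVcfRoundTrip:
    def test_write_read_consistency(self, small_dataset, tmp_path):
        _, matrices, _ = small_dataset
        path = tmp_path / "g.vcf"
        write_vcf(matrices, str(path))
        species_map = dict(zip(matrices[0].samples, matrices[0].species))
        back = {gm.gene_id: gm for gm in read_vcf(str(path), species_map)}
        nonempty = [gm for gm in matrices if gm.n_sites]
        assert len(back) == len(nonempty)
        for gm in nonempty:
            got = back[gm.gene_id]
            assert np.array_equal(got.positions, gm.positions)
            assert got.ref == gm.ref and got.alt == gm.alt
            assert np.array_equal(got.genotypes, gm.genotypes)


class TestCounts:
    def test_poisson_limit_variance_matches_mean(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, np.full(50_000, 40.0), dispersion=0.0)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)
        draws = _nb_draw(rng, np.full(50_000, 40.0), dispersion=0.2)
        assert draws.var() == pytest.approx(40 + 0.2 * 1600, rel=0.1)

    def test_node_truth_genes_have_separated_ranges(self):
        p = SimParams(n_genes=120, frac_de=0.2, frac_node=1.0, seed=9)
        counts, totals, meta, truth = gen_count_matrix(p)
        r = rpm(counts, totals)
        for tissue in ("leaf", "floral", "root"):
            node_genes = truth.df.index[truth.df[f"is_node_{tissue}"]]
            assert truth.df.loc[node_genes, f"is_de_{tissue}"].all()  # node => de
            meta_t = meta[meta["tissue"] == tissue]
            for g in node_genes:
                up = truth.df.loc[g, f"direction_{tissue}"]
                r_up = r.loc[g, meta_t.loc[meta_t["species"] == up, "sample_id"]]
                r_dn = r.loc[g, meta_t.loc[meta_t["species"] != up, "sample_id"]]
                assert r_up.min() > r_dn.max()
                assert r.loc[g, meta_t["sample_id"]].min() >= 1.0

    def test_non_de_genes_have_equal_species_means(self):
        p = SimParams(n_genes=400, frac_de=0.0, nb_dispersion=0.02, seed=3)
        counts, totals, meta, truth = gen_count_matrix(p)
        r = rpm(counts, totals)
        a = meta.loc[meta["species"] == "A", "sample_id"]
        b = meta.loc[meta["species"] == "B", "sample_id"]
        ratio = r[list(a)].mean(axis=1) / r[list(b)].mean(axis=1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)


class TestGoMap:
    def test_full_enrichment_gives_every_selected_gene_dual_terms(self, small_params):
        p = SimParams(n_genes=60, frac_selected=0.3, go_enrichment_frac=1.0, seed=12)
        _, _, truth = gen_gene_alignments(p)
        gomap, truth = gen_go_map(p, truth)
        for gene in truth.df.index[truth.df["is_selected"]]:
            terms = gomap.terms_of(gene)
            assert terms & ECOLOGICAL_TERMS and terms & REPRODUCTIVE_TERMS

    def test_focal_only_vocabulary(self):
        p = SimParams(n_genes=40, n_background_go_terms=0, seed=1)
        _, _, truth = gen_gene_alignments(p)
        gomap, _ = gen_go_map(p, truth)
        assert set(gomap.term_to_genes) <= (ECOLOGICAL_TERMS | REPRODUCTIVE_TERMS)

    def test_zero_enrichment_dual_rate_matches_marginal_product(self):
        p = SimParams(
            n_genes=4000, frac_selected=0.0, go_enrichment_frac=0.0,
            go_terms_per_gene=3.0, n_background_go_terms=10, seed=7,
        )
        from palmspec.synthetic_data import TruthTable

        truth = TruthTable([f"g{i}" for i in range(4000)])
        gomap, _ = gen_go_map(p, truth)
        has_eco = [bool(gomap.terms_of(g) & ECOLOGICAL_TERMS) for g in truth.df.index]
        has_rep = [bool(gomap.terms_of(g) & REPRODUCTIVE_TERMS) for g in truth.df.index]
        both = np.mean([e and r for e, r in zip(has_eco, has_rep)])
        # independence only approximate (terms drawn without replacement)
        assert both == pytest.approx(np.mean(has_eco) * np.mean(has_rep), abs=0.02)


class TestReads:
    def test_family_size_one_means_nothing_removed(self):
        from palmspec.dedup import dedup

        p = SimParams(
            n_read_families=40, dup_family_size_distribution={1: 1.0}, seed=3
        )
        reads, truth = gen_read_pairs(p)
        retained, report = dedup(reads)
        assert report.n_removed == 0

    def test_errors_confined_to_low_quality_bases(self):
        p = SimParams(n_read_families=50, seed=6)
        reads, truth = gen_read_pairs(p)
        by_family: dict[str, list] = {}
        fam_of = dict(zip(truth["read_id"], truth["family_id"]))
        for r in reads:
            by_family.setdefault(fam_of[r.id], []).append(r)
        for members in by_family.values():
            for r in members:
                for other in members:
                    for s1, s2, q1 in (
                        (r.seq1, other.seq1, r.qual1),
                        (r.seq2, other.seq2, r.qual2),
                    ):
                        for i, (x, y) in enumerate(zip(s1, s2)):
                            if x != y:
                                assert q1[i] < 7 or other_qual_low(other, r, i, s1 is r.seq1)


def other_qual_low(other, r, i, first_mate):
    q = other.qual1 if first_mate else other.qual2
    return q[i] < 7
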