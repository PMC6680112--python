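"""Synthetic two-species datasets with known truth.

The generator emulates the data structures produced by a two-species
transcriptome study: per-gene coding alignments carrying fixed inter-species
differences (with a configurable fraction of genes given an elevated
nonsynonymous fixation ratio), within-species polymorphism segregating at
Hardy–Weinberg proportions, negative-binomial expression counts with
species/tissue/batch structure and planted non-overlapping DE genes, GO maps
with optional dual ecological/reproductive annotation of selected genes, and
paired FASTQ reads organized into PCR-duplicate families.

Every output is a deterministic function of ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import CodonAlignment
from .codons import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    SITES_BY_CODON,
    STOP_CODONS,
    single_base_neighbors,
)
from .dedup import ReadPair
from .popgen import GenotypeMatrix
from .screen import ECOLOGICAL_TERMS, REPRODUCTIVE_TERMS

__all__ = [
    "SimParams",
    "TruthTable",
    "gen_gene_alignments",
    "gen_count_matrix",
    "gen_go_map",
    "gen_read_pairs",
    "haplotypes_from_genotypes",
    "write_vcf",
    "read_vcf",
]

TISSUES = ("leaf", "floral", "root")


@dataclass
class SimParams:
    """Study-condition parameters for the synthetic generator.

    Rates are per site; ``theta_within`` is the probability that a coding
    site segregates within a species, ``divergence_per_site`` the probability
    of a fixed inter-species difference. ``omega_*`` are target
    nonsynonymous:synonymous fixation ratios realized by biased acceptance
    of candidate substitutions.
    """

    n_genes: int = 200
    gene_length_codons: int = 200
    n_individuals_per_species: int = 10
    theta_within: float = 0.003
    divergence_per_site: float = 0.002
    frac_shared: float = 0.3
    frac_selected: float = 0.1
    omega_selected: float = 2.0
    omega_background: float = 0.2
    n_samples_per_tissue_species: int = 8
    nb_dispersion: float = 0.05
    lfc_de: float = 2.0
    frac_de: float = 0.1
    frac_node: float = 0.5
    lib_size_range: tuple[int, int] = (1_000_000, 5_000_000)
    dup_family_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.08}
    )
    n_read_families: int = 200
    read_length: int = 100
    low_quality_frac: float = 0.05
    error_at_low_quality: float = 0.5
    go_enrichment_frac: float = 0.8
    n_background_go_terms: int = 40
    go_terms_per_gene: float = 2.0
    species_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "theta_within",
            "divergence_per_site",
            "frac_shared",
            "frac_selected",
            "frac_de",
            "frac_node",
            "low_quality_frac",
            "error_at_low_quality",
            "go_enrichment_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.omega_selected <= 0 or self.omega_background <= 0:
            raise ValueError("omega targets must be positive")
        if self.gene_length_codons < 10:
            raise ValueError("gene_length_codons must be >= 10")
        for name in ("n_genes", "n_individuals_per_species", "n_samples_per_tissue_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("lib_size_range must be a positive increasing pair")
        probs = self.dup_family_size_distribution
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(
            k < 1 for k in probs
        ):
            raise ValueError("dup_family_size_distribution must be a distribution over sizes >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-scoped generator: one master seed, independent streams."""
        return np.random.default_rng([self.seed, _STAGE_IDS[stage]])


_STAGE_IDS = {"alignments": 1, "counts": 2, "go": 3, "reads": 4}


class TruthTable:
    """Per-gene ground truth, accumulated stage by stage.

    Backed by a DataFrame indexed by gene_id; ``is_node_<tissue>`` implies
    ``is_de_<tissue>`` by construction.
    """

    def __init__(self, genes: Sequence[str]) -> None:
        self.df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))

    def set_column(self, name: str, values) -> None:
        self.df[name] = values

    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        obj = cls(list(df.index))
        obj.df = df
        return obj


# ----------------------------------------------------------------- alignments


def _random_orf(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = ["ATG"] + list(rng.choice(SENSE_CODONS, size=n_codons - 1))
    return codons


def _candidate_changes(codon: str) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """Non-stop single-base changes of a codon, split syn / nonsyn."""
    syn, nonsyn = [], []
    for pos in range(3):
        for neigh in single_base_neighbors(codon, pos):
            if neigh in STOP_CODONS:
                continue
            (syn if CODON_TO_AA[neigh] == CODON_TO_AA[codon] else nonsyn).append(
                (pos, neigh[pos])
            )
    return syn, nonsyn


def _sfs_frequency(rng: np.random.Generator, n_alleles: int) -> float:
    """Derived-allele frequency from a neutral-shaped 1/i spectrum."""
    i = np.arange(1, n_alleles)
    w = 1.0 / i
    return float(rng.choice(i, p=w / w.sum())) / n_alleles


def _draw_polymorphic_genotypes(
    rng: np.random.Generator, n_ind: int
) -> np.ndarray:
    """HW genotype dosages for one species, redrawn until sample-polymorphic."""
    while True:
        p = _sfs_frequency(rng, 2 * n_ind)
        g = rng.binomial(2, p, size=n_ind).astype(np.int8)
        if 0 < g.sum() < 2 * n_ind:
            return g


def gen_gene_alignments(
    params: SimParams,
) -> tuple[list[CodonAlignment], list[GenotypeMatrix], TruthTable]:
    """Generate per-gene alignments, genotype matrices and selection truth.

    Each gene carries at most one variant site per codon. Fixed differences
    are applied to the species-B consensus with nonsynonymous:synonymous
    proportions targeting the gene's true omega; polymorphisms are placed
    independently per species (a configurable fraction shared between them)
    and expanded to Hardy–Weinberg diploid genotypes. Alignments contain the
    two species consensus sequences plus two haplotypes per individual, so
    the genotype matrix and the alignment describe the same variants.
    """
    params.validate()
    rng = params.rng("alignments")
    sp_a, sp_b = params.species_labels
    n_ind = params.n_individuals_per_species
    n_sites = 3 * params.gene_length_codons

    gene_ids = [f"gene{str(i).zfill(4)}" for i in range(params.n_genes)]
    truth = TruthTable(gene_ids)
    n_sel = int(round(params.frac_selected * params.n_genes))
    selected = np.zeros(params.n_genes, dtype=bool)
    selected[rng.choice(params.n_genes, size=n_sel, replace=False)] = True

    samples = [f"{sp}{i}" for sp in (sp_a, sp_b) for i in range(n_ind)]
    species_arr = np.array([sp_a] * n_ind + [sp_b] * n_ind)

    alignments: list[CodonAlignment] = []
    matrices: list[GenotypeMatrix] = []
    stats_rows = []
    for gi, gene_id in enumerate(gene_ids):
        omega_true = params.omega_selected if selected[gi] else params.omega_background
        codons_a = _random_orf(rng, params.gene_length_codons)
        codons_b = list(codons_a)
        free_codons = list(rng.permutation(np.arange(1, params.gene_length_codons)))

        # --- fixed differences, biased acceptance toward the target omega
        n_fixed = rng.binomial(n_sites, params.divergence_per_site)
        syn_sites = sum(SITES_BY_CODON[c][0] for c in codons_a)
        nonsyn_sites = n_sites - syn_sites
        p_nonsyn = (
            omega_true * nonsyn_sites / (omega_true * nonsyn_sites + syn_sites)
        )
        want_nonsyn = int(rng.binomial(n_fixed, p_nonsyn))
        want_syn = n_fixed - want_nonsyn
        got_nonsyn = got_syn = 0
        fixed_records = []  # (codon_idx, within_pos, ref_base, alt_base, class)
        while (got_nonsyn < want_nonsyn or got_syn < want_syn) and free_codons:
            ci = int(free_codons.pop())
            syn_opts, nonsyn_opts = _candidate_changes(codons_a[ci])
            if got_nonsyn < want_nonsyn and nonsyn_opts:
                pos, base = nonsyn_opts[rng.integers(len(nonsyn_opts))]
                cls = "nonsynonymous"
                got_nonsyn += 1
            elif got_syn < want_syn and syn_opts:
                pos, base = syn_opts[rng.integers(len(syn_opts))]
                cls = "synonymous"
                got_syn += 1
            else:
                continue
            ref_base = codons_a[ci][pos]
            codons_b[ci] = codons_b[ci][:pos] + base + codons_b[ci][pos + 1 :]
            fixed_records.append((ci, pos, ref_base, base, cls))

        # --- polymorphisms (shared or private), one per remaining codon
        poly_records = []  # (codon_idx, pos, ref, alt, {species: dosages})
        n_poly_a = rng.binomial(n_sites, params.theta_within)
        n_poly_b = rng.binomial(n_sites, params.theta_within)
        n_shared = rng.binomial(min(n_poly_a, n_poly_b), params.frac_shared)
        plan = (
            [("both",)] * n_shared
            + [(sp_a,)] * (n_poly_a - n_shared)
            + [(sp_b,)] * (n_poly_b - n_shared)
        )
        for (who,) in plan:
            if not free_codons:
                break
            ci = int(free_codons.pop())
            syn_opts, nonsyn_opts = _candidate_changes(codons_a[ci])
            opts = syn_opts + nonsyn_opts
            pos, base = opts[rng.integers(len(opts))]
            ref_base = codons_a[ci][pos]
            dosages = {}
            for sp in (sp_a, sp_b):
                if who in ("both", sp):
                    dosages[sp] = _draw_polymorphic_genotypes(rng, n_ind)
                else:
                    dosages[sp] = np.zeros(n_ind, dtype=np.int8)
            poly_records.append((ci, pos, ref_base, base, dosages))

        # --- assemble site table sorted by position
        sites = []
        for ci, pos, ref, alt, cls in fixed_records:
            dos = np.concatenate(
                [np.zeros(n_ind, dtype=np.int8), np.full(n_ind, 2, dtype=np.int8)]
            )
            sites.append((3 * ci + pos + 1, ref, alt, dos, cls, "fixed"))
        for ci, pos, ref, alt, dosages in poly_records:
            dos = np.concatenate([dosages[sp_a], dosages[sp_b]])
            cls = (
                "synonymous"
                if CODON_TO_AA[codons_a[ci]]
                == CODON_TO_AA[codons_a[ci][:pos] + alt + codons_a[ci][pos + 1 :]]
                else "nonsynonymous"
            )
            a_poly = 0 < dosages[sp_a].sum() < 2 * n_ind
            b_poly = 0 < dosages[sp_b].sum() < 2 * n_ind
            kind = "shared" if (a_poly and b_poly) else f"private-{sp_a if a_poly else sp_b}"
            sites.append((3 * ci + pos + 1, ref, alt, dos, cls, kind))
        sites.sort(key=lambda s: s[0])

        positions = np.array([s[0] for s in sites], dtype=int)
        genotypes = (
            np.vstack([s[3] for s in sites])
            if sites
            else np.zeros((0, 2 * n_ind), dtype=np.int8)
        )
        gm = GenotypeMatrix(
            gene_id=gene_id,
            positions=positions,
            ref=[s[1] for s in sites],
            alt=[s[2] for s in sites],
            genotypes=genotypes,
            samples=samples,
            species=species_arr,
        )
        matrices.append(gm)

        seq_a = "".join(codons_a)
        seq_b = "".join(codons_b)
        seqs = {f"{sp_a}_consensus": seq_a, f"{sp_b}_consensus": seq_b}
        haplos = haplotypes_from_genotypes(gm, {sp_a: seq_a, sp_b: seq_b}, rng)
        seqs.update(haplos)
        alignments.append(CodonAlignment(gene_id=gene_id, sequences=seqs))

        stats_rows.append(
            {
                "is_selected": bool(selected[gi]),
                "omega_true": omega_true,
                "n_fixed_nonsyn": sum(1 for s in sites if s[5] == "fixed" and s[4] == "nonsynonymous"),
                "n_fixed_syn": sum(1 for s in sites if s[5] == "fixed" and s[4] == "synonymous"),
                "n_poly": sum(1 for s in sites if s[5] != "fixed"),
                "n_poly_nonsyn": sum(
                    1 for s in sites if s[5] != "fixed" and s[4] == "nonsynonymous"
                ),
                "n_shared": sum(1 for s in sites if s[5] == "shared"),
                "n_snps": len(sites),
            }
        )

    stats = pd.DataFrame(stats_rows, index=truth.df.index)
    for col in stats.columns:
        truth.set_column(col, stats[col])
    return alignments, matrices, truth


def haplotypes_from_genotypes(
    gm: GenotypeMatrix,
    species_consensus: dict[str, str],
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Expand diploid dosages to two haplotype sequences per individual.

    Heterozygous sites place the alternate allele on a random haplotype
    (deterministic under a seeded generator). The backbone for each
    individual is its species consensus with SNP sites reset to REF.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    out: dict[str, str] = {}
    for col, (sample, sp) in enumerate(zip(gm.samples, gm.species)):
        base = list(species_consensus[sp])
        for pos, ref in zip(gm.positions, gm.ref):
            base[pos - 1] = ref
        hap0, hap1 = list(base), list(base)
        for row, pos, alt in zip(gm.genotypes, gm.positions, gm.alt):
            d = int(row[col])
            if d <= 0:
                continue
            if d == 2:
                hap0[pos - 1] = alt
                hap1[pos - 1] = alt
            else:
                (hap0 if rng.random() < 0.5 else hap1)[pos - 1] = alt
        out[f"{sample}_h1"] = "".join(hap0)
        out[f"{sample}_h2"] = "".join(hap1)
    return out


# --------------------------------------------------------------------- counts


def _sample_meta(params: SimParams) -> pd.DataFrame:
    sp_a, sp_b = params.species_labels
    rows = []
    for tissue in TISSUES:
        for sp in (sp_a, sp_b):
            for i in range(params.n_samples_per_tissue_species):
                soil = "NA"
                if sp == sp_a:
                    soil = "calcarenite" if i % 2 == 0 else "volcanic"
                rows.append(
                    {
                        "sample_id": f"{sp}_{tissue}_{i}",
                        "species": sp,
                        "tissue": tissue,
                        "soil": soil,
                        "trip": f"trip{i % 3 + 1}",
                    }
                )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean^2); Poisson in the limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


TRIP_LOG2_EFFECTS = {"trip1": -0.25, "trip2": 0.0, "trip3": 0.25}


def gen_count_matrix(
    params: SimParams, truth: TruthTable | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, TruthTable]:
    """Simulate counts, library totals and metadata; extend the truth table.

    DE-truth genes receive a log2 fold-change of ``lfc_de`` between species
    in one designated tissue; a ``frac_node`` share of them is additionally
    forced to strict per-species rpm range separation (with every sample of
    that tissue at rpm >= 1) by redrawing the gene's counts in that tissue.
    Batch (trip) effects are additive on the log2 mean. Non-DE genes have
    identical species means.
    """
    params.validate()
    rng = params.rng("counts")
    sp_a, sp_b = params.species_labels
    meta = _sample_meta(params)
    n_samples = len(meta)

    gene_ids = (
        list(truth.df.index)
        if truth is not None
        else [f"gene{str(i).zfill(4)}" for i in range(params.n_genes)]
    )
    n_genes = len(gene_ids)
    truth = truth if truth is not None else TruthTable(gene_ids)

    lib_sizes = rng.integers(
        params.lib_size_range[0], params.lib_size_range[1] + 1, size=n_samples
    )
    library_totals = pd.Series(lib_sizes, index=meta["sample_id"], dtype=float)

    base_rpm = np.exp(rng.normal(np.log(30.0), 1.2, size=n_genes))

    n_de = int(round(params.frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_tissue = rng.choice(TISSUES, size=n_de)
    n_node = int(round(params.frac_node * n_de))
    node_flag = np.zeros(n_de, dtype=bool)
    node_flag[rng.choice(n_de, size=n_node, replace=False)] = True
    up_species = rng.choice([sp_a, sp_b], size=n_de)
    # keep planted DE genes comfortably above the expression filter
    base_rpm[de_idx] = np.maximum(base_rpm[de_idx], 30.0)

    is_de = {t: np.zeros(n_genes, dtype=bool) for t in TISSUES}
    is_node = {t: np.zeros(n_genes, dtype=bool) for t in TISSUES}
    direction = {t: np.array([""] * n_genes, dtype=object) for t in TISSUES}
    for j, g in enumerate(de_idx):
        t = de_tissue[j]
        is_de[t][g] = True
        is_node[t][g] = node_flag[j]
        direction[t][g] = up_species[j]

    trip_eff = meta["trip"].map(TRIP_LOG2_EFFECTS).to_numpy()
    sp_col = meta["species"].to_numpy()
    tissue_col = meta["tissue"].to_numpy()
    scale = library_totals.to_numpy() / 1e6

    log2_mu = np.tile(np.log2(base_rpm)[:, None], (1, n_samples)) + trip_eff[None, :]
    for j, g in enumerate(de_idx):
        t = de_tissue[j]
        in_t = tissue_col == t
        up = sp_col == up_species[j]
        log2_mu[g, in_t & up] += params.lfc_de / 2.0
        log2_mu[g, in_t & ~up] -= params.lfc_de / 2.0
    mu = (2.0**log2_mu) * scale[None, :]

    counts = _nb_draw(rng, mu, params.nb_dispersion)

    # enforce the NODE construction: strict range separation at rpm >= 1
    for j, g in enumerate(de_idx):
        if not node_flag[j]:
            continue
        t = de_tissue[j]
        in_t = np.flatnonzero(tissue_col == t)
        up = sp_col[in_t] == up_species[j]
        for _ in range(1000):
            r = counts[g, in_t] * 1e6 / library_totals.to_numpy()[in_t]
            if (r >= 1.0).all() and r[up].min() > r[~up].max():
                break
            counts[g, in_t] = _nb_draw(rng, mu[g, in_t], params.nb_dispersion)
        else:
            raise RuntimeError(
                f"could not realize NODE separation for gene {gene_ids[g]}; "
                "raise lfc_de or lower nb_dispersion"
            )

    count_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=list(meta["sample_id"])
    )
    for t in TISSUES:
        truth.set_column(f"is_de_{t}", is_de[t])
        truth.set_column(f"is_node_{t}", is_node[t])
        truth.set_column(f"direction_{t}", direction[t])
    return count_df, library_totals, meta, truth


# ------------------------------------------------------------------------- GO


def gen_go_map(params: SimParams, truth: TruthTable):
    """GO annotations: background vocabulary plus focal-term enrichment.

    Every gene draws a Poisson number of terms uniformly from the full
    vocabulary (six focal ids plus ``n_background_go_terms`` generic ids);
    a ``go_enrichment_frac`` share of selected genes additionally receives
    at least one ecological and one reproductive focal term.
    """
    from .screen import GoMap

    params.validate()
    rng = params.rng("go")
    eco = sorted(ECOLOGICAL_TERMS)
    rep = sorted(REPRODUCTIVE_TERMS)
    background_terms = [f"GO:{1000000 + i:07d}" for i in range(params.n_background_go_terms)]
    vocab = eco + rep + background_terms

    mapping: dict[str, set] = {}
    dual_truth = []
    genes = list(truth.df.index)
    is_selected = (
        truth.df["is_selected"].to_numpy()
        if "is_selected" in truth.df
        else np.zeros(len(genes), dtype=bool)
    )
    for gene, sel in zip(genes, is_selected):
        k = rng.poisson(params.go_terms_per_gene)
        terms = set(rng.choice(vocab, size=min(k, len(vocab)), replace=False)) if k else set()
        planted = False
        if sel and rng.random() < params.go_enrichment_frac:
            terms.add(eco[rng.integers(len(eco))])
            terms.add(rep[rng.integers(len(rep))])
            planted = True
        mapping[gene] = terms
        dual_truth.append(planted)
    truth.set_column("go_dual_planted", dual_truth)
    truth.set_column(
        "go_terms", [",".join(sorted(mapping[g])) for g in genes]
    )
    descriptions = {t: f"synthetic term {t}" for t in vocab}
    return GoMap(mapping, descriptions), truth


# ---------------------------------------------------------------------- reads


def gen_read_pairs(params: SimParams) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired reads in PCR-duplicate families with errors only at Q < 7 bases.

    Each family derives from one source fragment; member copies get
    independent quality strings (a ``low_quality_frac`` share of bases below
    7) and sequencing errors planted exclusively at those low-quality
    positions. Returns the pairs and a truth frame (read_id, family_id,
    family_size).
    """
    params.validate()
    rng = params.rng("reads")
    sizes = np.array(sorted(params.dup_family_size_distribution))
    probs = np.array([params.dup_family_size_distribution[s] for s in sizes])
    read_len = params.read_length

    pairs: list[ReadPair] = []
    rows = []
    for fam in range(params.n_read_families):
        size = int(rng.choice(sizes, p=probs))
        fragment = "".join(rng.choice(list(BASES), size=2 * read_len))
        for copy in range(size):
            qual = rng.integers(25, 41, size=2 * read_len)
            low = rng.random(2 * read_len) < params.low_quality_frac
            qual[low] = rng.integers(2, 7, size=int(low.sum()))
            seq = list(fragment)
            err_at = np.flatnonzero(low & (rng.random(2 * read_len) < params.error_at_low_quality))
            for pos in err_at:
                seq[pos] = rng.choice([b for b in BASES if b != fragment[pos]])
            seq_str = "".join(seq)
            rid = f"fam{fam:05d}_copy{copy}"
            pairs.append(
                ReadPair(
                    id=rid,
                    seq1=seq_str[:read_len],
                    seq2=seq_str[read_len:],
                    qual1=list(qual[:read_len]),
                    qual2=list(qual[read_len:]),
                )
            )
            rows.append({"read_id": rid, "family_id": f"fam{fam:05d}", "family_size": size})
    truth = pd.DataFrame(rows)
    return pairs, truth


# --------------------------------------------------------------------- VCF IO


def write_vcf(matrices: Sequence[GenotypeMatrix], path: str) -> None:
    """One VCF for all genes: CHROM = gene id, 1-based positions, GT only."""
    if not matrices:
        raise ValueError("no genotype matrices to write")
    samples = matrices[0].samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for gm in matrices:
            fh.write(f"##contig=<ID={gm.gene_id}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for gm in matrices:
            for pos, ref, alt, row in zip(gm.positions, gm.ref, gm.alt, gm.genotypes):
                calls = "\t".join(gt_str[int(d)] for d in row)
                fh.write(f"{gm.gene_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str, species_map: dict[str, str]) -> list[GenotypeMatrix]:
    """Parse a biallelic-SNP VCF into per-gene genotype matrices.

    ``species_map`` assigns each sample to a species; GQ and DP FORMAT
    fields are carried along when present.
    """
    import pysam

    out: dict[str, dict] = {}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        species = np.array([species_map[s] for s in samples])
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue  # SNPs only
            store = out.setdefault(
                rec.chrom,
                {"pos": [], "ref": [], "alt": [], "geno": [], "gq": [], "dp": [], "qual": []},
            )
            dosages, gqs, dps = [], [], []
            has_gq = has_dp = False
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages.append(-1)
                else:
                    dosages.append(int(sum(gt)))
                gq = call.get("GQ")
                dp = call.get("DP")
                has_gq |= gq is not None
                has_dp |= dp is not None
                gqs.append(-1 if gq is None else gq)
                dps.append(-1 if dp is None else dp)
            store["pos"].append(rec.pos)
            store["ref"].append(rec.ref)
            store["alt"].append(rec.alts[0])
            store["geno"].append(dosages)
            store["gq"].append(gqs if has_gq else None)
            store["dp"].append(dps if has_dp else None)
            store["qual"].append(rec.qual)
    matrices = []
    for gene_id, store in out.items():
        gq = None
        if all(x is not None for x in store["gq"]) and store["gq"]:
            gq = np.array(store["gq"], dtype=float)
        dp = None
        if all(x is not None for x in store["dp"]) and store["dp"]:
            dp = np.array(store["dp"], dtype=float)
        qual = None
        if all(q is not None for q in store["qual"]) and store["qual"]:
            qual = np.array(store["qual"], dtype=float)
        matrices.append(
            GenotypeMatrix(
                gene_id=gene_id,
                positions=np.array(store["pos"], dtype=int),
                ref=store["ref"],
                alt=store["alt"],
                genotypes=np.array(store["geno"], dtype=np.int8),
                samples=samples,
                species=np.array([species_map[s] for s in samples]),
                gq=gq,
                dp=dp,
                site_qual=qual,
            )
        )
    return matrices
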