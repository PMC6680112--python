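"""Per-gene population-genetic summaries from diploid SNP genotypes.

The substrate is a :class:`GenotypeMatrix` of biallelic sites x diploid
individuals with species labels. Statistics follow the classical sequence
formulations: diploid genotypes are expanded to 2n allele samples, so pi,
Tajima's D and the Fu & Li starred statistics are the standard
frequency-spectrum quantities; differentiation uses the Weir–Cockerham theta
estimator (ratio of sums across sites) and absolute divergence Dxy the
per-site inter-population mismatch probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PopgenSummary",
    "filter_genotypes",
    "classify_snps",
    "nucleotide_diversity",
    "tajimas_d",
    "fu_li_star",
    "fst",
    "dxy",
    "observed_heterozygosity",
    "species_consensus",
    "summarize_gene",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x diploid individuals for one gene.

    ``genotypes[s, i]`` is the alt-allele dosage (0, 1, 2) or -1 for a
    missing call. Positions are 1-based within the gene and strictly
    increasing.
    """

    gene_id: str
    positions: np.ndarray  # (S,) int, 1-based
    ref: list[str]
    alt: list[str]
    genotypes: np.ndarray  # (S, n) int8 dosages, -1 missing
    samples: list[str]
    species: np.ndarray  # (n,) labels, two distinct values expected
    gq: np.ndarray | None = None  # (S, n) genotype quality
    dp: np.ndarray | None = None  # (S, n) depth
    site_qual: np.ndarray | None = None  # (S,) VCF QUAL

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.species = np.asarray(self.species)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites x individuals)")
        if len(self.positions) != self.genotypes.shape[0]:
            raise ValueError("positions / genotype row mismatch")
        if len(self.samples) != self.genotypes.shape[1]:
            raise ValueError("samples / genotype column mismatch")
        if len(self.species) != len(self.samples):
            raise ValueError("every individual needs a species label")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def species_mask(self, label: str) -> np.ndarray:
        return self.species == label

    def species_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.species:
            if s not in seen:
                seen.append(s)
        return seen

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            positions=self.positions[idx],
            ref=[self.ref[i] for i in np.flatnonzero(idx)]
            if idx.dtype == bool
            else [self.ref[i] for i in idx],
            alt=[self.alt[i] for i in np.flatnonzero(idx)]
            if idx.dtype == bool
            else [self.alt[i] for i in idx],
            genotypes=self.genotypes[idx],
            gq=self.gq[idx] if self.gq is not None else None,
            dp=self.dp[idx] if self.dp is not None else None,
            site_qual=self.site_qual[idx] if self.site_qual is not None else None,
        )


@dataclass
class PopgenSummary:
    gene_id: str
    n_snps: int
    pi_per_site: dict
    tajimas_d: dict
    fu_li_d_star: dict
    fu_li_f_star: dict
    het_obs: dict
    fst: float | None
    dxy_per_site: float | None
    class_counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------- filtering


def filter_genotypes(
    gm: GenotypeMatrix,
    min_site_qual: float = 20.0,
    min_gq: float = 20.0,
    min_dp: float = 3.0,
    maf: float = 0.1,
    max_missing: float = 0.7,
) -> GenotypeMatrix:
    """Quality/frequency filter mirroring a VCFtools-style pass.

    Genotypes with GQ < ``min_gq`` or DP < ``min_dp`` are set missing (when
    those annotations exist); sites with QUAL < ``min_site_qual`` (when
    present), pooled minor-allele frequency < ``maf`` over non-missing
    alleles, or call rate < ``max_missing`` are removed.
    """
    geno = gm.genotypes.copy()
    if gm.gq is not None:
        geno[gm.gq < min_gq] = MISSING
    if gm.dp is not None:
        geno[gm.dp < min_dp] = MISSING
    called = geno != MISSING
    n_ind = geno.shape[1] if geno.ndim == 2 else 0
    with np.errstate(invalid="ignore"):
        call_rate = called.sum(axis=1) / max(n_ind, 1)
        alt_alleles = np.where(called, geno, 0).sum(axis=1).astype(float)
        total_alleles = 2.0 * called.sum(axis=1)
        p = np.divide(
            alt_alleles,
            total_alleles,
            out=np.zeros_like(alt_alleles),
            where=total_alleles > 0,
        )
    minor = np.minimum(p, 1.0 - p)
    keep = (call_rate >= max_missing) & (minor >= maf) & (total_alleles > 0)
    if gm.site_qual is not None:
        keep &= gm.site_qual >= min_site_qual
    out = gm.take_sites(keep)
    out.genotypes = geno[keep]
    return out


# ----------------------------------------------------------- classification


def _species_allele_sets(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = gm.species_labels()
    if len(labels) != 2:
        raise ValueError(f"expected two species, found {labels}")
    return labels, gm.species_mask(labels[0]), gm.species_mask(labels[1])


def classify_snps(gm: GenotypeMatrix) -> list[str]:
    """Per-site label: fixed / shared / private-A / private-B / uncallable.

    fixed: the two species carry disjoint allele sets, each monomorphic;
    shared: both polymorphic; private: exactly one polymorphic. A site with
    no non-missing call in one species is ``uncallable``.
    """
    labels, mask_a, mask_b = _species_allele_sets(gm)
    out: list[str] = []
    for row in gm.genotypes:
        sets = []
        for mask in (mask_a, mask_b):
            g = row[mask]
            g = g[g != MISSING]
            alleles = set()
            if (g > 0).any():
                alleles.add(1)
            if (g < 2).any():
                alleles.add(0)
            if len(g) == 0:
                alleles = None
            sets.append(alleles)
        sa, sb = sets
        if sa is None or sb is None:
            out.append("uncallable")
        elif len(sa) == 1 and len(sb) == 1:
            out.append("fixed" if sa != sb else "monomorphic")
        elif len(sa) > 1 and len(sb) > 1:
            out.append("shared")
        elif len(sa) > 1:
            out.append(f"private-{labels[0]}")
        else:
            out.append(f"private-{labels[1]}")
    return out


# ------------------------------------------------------------- diversity


def _allele_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt alleles, total non-missing alleles) per site for diploid dosages."""
    called = geno != MISSING
    alt = np.where(called, geno, 0).sum(axis=1).astype(float)
    tot = 2.0 * called.sum(axis=1).astype(float)
    return alt, tot


def nucleotide_diversity(
    gm: GenotypeMatrix, species: str | None = None, gene_length: int = 0
) -> float:
    """Per-site pi: sum over sites of 2*p*q*n/(n-1), divided by gene length."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    geno = gm.genotypes if species is None else gm.genotypes[:, gm.species_mask(species)]
    alt, tot = _allele_counts(geno)
    usable = tot >= 2
    alt, tot = alt[usable], tot[usable]
    if len(alt) == 0:
        return 0.0
    p = alt / tot
    pi_sites = 2.0 * p * (1.0 - p) * tot / (tot - 1.0)
    return float(pi_sites.sum()) / gene_length


def mean_pairwise_differences(gm: GenotypeMatrix, species: str | None = None) -> float:
    """Total mean pairwise differences (pi summed over sites, not per site)."""
    geno = gm.genotypes if species is None else gm.genotypes[:, gm.species_mask(species)]
    alt, tot = _allele_counts(geno)
    usable = tot >= 2
    alt, tot = alt[usable], tot[usable]
    if len(alt) == 0:
        return 0.0
    p = alt / tot
    return float((2.0 * p * (1.0 - p) * tot / (tot - 1.0)).sum())


# --------------------------------------------------- frequency-spectrum tests


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from segregating sites, sample size (alleles) and total pi.

    Standard constants a1, a2, b1, b2, c1, c2, e1, e2; raises for S = 0
    (undefined rather than zero) or n < 4.
    """
    if S < 1:
        raise ValueError("Tajima's D undefined for S = 0")
    if n < 4:
        raise ValueError("need at least 4 sequences")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (pi_total - S / a1) / math.sqrt(var)


def fu_li_star(S: int, n: int, n_singletons: int, pi_total: float) -> tuple[float, float]:
    """Fu & Li's outgroup-free D* and F* from within-sample singleton counts.

    Uses the corrected variance constants in general use (the starred
    statistics as implemented in standard popgen libraries). ``n_singletons``
    counts sites whose rarer allele occurs in exactly one of the ``n``
    sampled alleles.
    """
    if S < 1:
        raise ValueError("undefined for S = 0")
    if n < 4:
        raise ValueError("need at least 4 sequences")
    nf = float(n)
    a = _harmonic(n)
    b = _harmonic(n, 2)
    a1 = a + 1.0 / nf  # a_{n+1}
    cn = 2.0 * (nf * a - 2.0 * (nf - 1.0)) / ((nf - 1.0) * (nf - 2.0))
    dn = (
        cn
        + (nf - 2.0) / (nf - 1.0) ** 2
        + (2.0 / (nf - 1.0)) * (1.5 - (2.0 * a1 - 3.0) / (nf - 2.0) - 1.0 / nf)
    )
    vD = (
        (nf / (nf - 1.0)) ** 2 * b
        + a**2 * dn
        - 2.0 * (nf * a * (a + 1.0)) / (nf - 1.0) ** 2
    ) / (a**2 + b)
    uD = (nf / (nf - 1.0)) * (a - nf / (nf - 1.0)) - vD
    d_star = ((nf / (nf - 1.0)) * S - a * n_singletons) / math.sqrt(
        uD * S + vD * S**2
    )
    vF = (
        dn
        + 2.0 * (nf**2 + nf + 3.0) / (9.0 * nf * (nf - 1.0))
        - (2.0 / (nf - 1.0)) * (4.0 * b - 6.0 + 8.0 / nf)
    ) / (a**2 + b)
    uF = (
        nf / (nf - 1.0)
        + (nf + 1.0) / (3.0 * (nf - 1.0))
        - 4.0 / (nf * (nf - 1.0))
        + 2.0 * (nf + 1.0) / (nf - 1.0) ** 2 * (a1 - 2.0 * nf / (nf + 1.0))
    ) / a - vF
    f_star = (pi_total - ((nf - 1.0) / nf) * n_singletons) / math.sqrt(
        uF * S + vF * S**2
    )
    return d_star, f_star


def spectrum_stats(gm: GenotypeMatrix, species: str | None = None) -> dict:
    """S, n, singleton count, total pi and the D/D*/F* statistics for a sample."""
    geno = gm.genotypes if species is None else gm.genotypes[:, gm.species_mask(species)]
    alt, tot = _allele_counts(geno)
    seg = (alt > 0) & (alt < tot) & (tot >= 2)
    S = int(seg.sum())
    # n: modal number of sampled alleles across segregating sites
    n = int(np.max(tot[seg])) if S else int(np.max(tot)) if len(tot) else 0
    minor = np.minimum(alt[seg], tot[seg] - alt[seg])
    singletons = int((minor == 1).sum())
    pi_total = mean_pairwise_differences(gm, species)
    out = {"S": S, "n": n, "singletons": singletons, "pi_total": pi_total}
    if S >= 1 and n >= 4:
        out["tajimas_d"] = tajimas_d(S, n, pi_total)
        d_star, f_star = fu_li_star(S, n, singletons, pi_total)
        out["fu_li_d_star"] = d_star
        out["fu_li_f_star"] = f_star
    else:
        out["tajimas_d"] = out["fu_li_d_star"] = out["fu_li_f_star"] = None
    return out


# ------------------------------------------------------------ differentiation


def fst(gm: GenotypeMatrix) -> float | None:
    """Weir–Cockerham theta between the two species, ratio of sums over sites.

    Sites monomorphic across both species are skipped; estimates may be
    slightly negative and are reported as-is. None when no usable site
    remains.
    """
    _, mask_a, mask_b = _species_allele_sets(gm)
    num = den = 0.0
    any_site = False
    for row in gm.genotypes:
        comps = _wc_site_components(row, mask_a, mask_b)
        if comps is None:
            continue
        a_comp, b_comp, c_comp = comps
        any_site = True
        num += a_comp
        den += a_comp + b_comp + c_comp
    if not any_site or den == 0.0:
        return None
    return num / den


def _wc_site_components(
    row: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> tuple[float, float, float] | None:
    """Weir & Cockerham (1984) a, b, c variance components at one site."""
    r = 2.0
    stats = []
    for mask in (mask_a, mask_b):
        g = row[mask]
        g = g[g != MISSING]
        if len(g) == 0:
            return None
        n_i = float(len(g))
        p_i = g.sum() / (2.0 * n_i)
        h_i = float((g == 1).sum()) / n_i
        stats.append((n_i, p_i, h_i))
    n1, p1, h1 = stats[0]
    n2, p2, h2 = stats[1]
    if n1 < 2 or n2 < 2:
        return None
    p_all = (n1 * p1 + n2 * p2) / (n1 + n2)
    if p_all in (0.0, 1.0):
        return None  # monomorphic overall
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
    s2 = (n1 * (p1 - p_all) ** 2 + n2 * (p2 - p_all) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1.0))
        * (p_all * (1.0 - p_all) - s2 * (r - 1.0) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        p_all * (1.0 - p_all)
        - s2 * (r - 1.0) / r
        - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def dxy(gm: GenotypeMatrix, gene_length: int) -> float:
    """Absolute divergence per site: mean inter-species mismatch probability.

    (1/L) * sum over sites of p_A(1-p_B) + p_B(1-p_A).
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    _, mask_a, mask_b = _species_allele_sets(gm)
    total = 0.0
    for row in gm.genotypes:
        ps = []
        for mask in (mask_a, mask_b):
            g = row[mask]
            g = g[g != MISSING]
            if len(g) == 0:
                ps = None
                break
            ps.append(g.sum() / (2.0 * len(g)))
        if ps is None:
            continue
        pa, pb = ps
        total += pa * (1.0 - pb) + pb * (1.0 - pa)
    return total / gene_length


def observed_heterozygosity(gm: GenotypeMatrix, species: str | None = None) -> float:
    """Fraction of non-missing genotypes that are heterozygous, over all sites."""
    geno = gm.genotypes if species is None else gm.genotypes[:, gm.species_mask(species)]
    called = geno != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return 0.0
    return float((geno == 1).sum()) / n_called


# ---------------------------------------------------------------- consensus


def species_consensus(
    gm: GenotypeMatrix, reference: str, species: str
) -> str:
    """Species consensus: substitute the within-species major allele per site.

    Frequency ties keep the reference allele. 1-based positions index into
    ``reference``; a REF allele that contradicts the reference base is an
    error.
    """
    if gm.n_sites and gm.positions.max() > len(reference):
        raise ValueError("reference shorter than max SNP position")
    seq = list(reference.upper())
    mask = gm.species_mask(species)
    for row, pos, ref_al, alt_al in zip(
        gm.genotypes, gm.positions, gm.ref, gm.alt
    ):
        if seq[pos - 1] != ref_al.upper():
            raise ValueError(
                f"{gm.gene_id}: REF {ref_al} at position {pos} contradicts "
                f"reference base {seq[pos - 1]}"
            )
        g = row[mask]
        g = g[g != MISSING]
        if len(g) == 0:
            continue
        p_alt = g.sum() / (2.0 * len(g))
        if p_alt > 0.5:
            seq[pos - 1] = alt_al.upper()
    return "".join(seq)


# ------------------------------------------------------------------ summary


def summarize_gene(gm: GenotypeMatrix, gene_length: int) -> PopgenSummary:
    """All per-gene popgen summaries in one record."""
    labels = gm.species_labels()
    pi = {sp: nucleotide_diversity(gm, sp, gene_length) for sp in labels}
    pi["all"] = nucleotide_diversity(gm, None, gene_length)
    spec = {sp: spectrum_stats(gm, sp) for sp in labels}
    spec["all"] = spectrum_stats(gm, None)
    classes = classify_snps(gm)
    counts: dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    return PopgenSummary(
        gene_id=gm.gene_id,
        n_snps=gm.n_sites,
        pi_per_site=pi,
        tajimas_d={k: v["tajimas_d"] for k, v in spec.items()},
        fu_li_d_star={k: v["fu_li_d_star"] for k, v in spec.items()},
        fu_li_f_star={k: v["fu_li_f_star"] for k, v in spec.items()},
        het_obs={sp: observed_heterozygosity(gm, sp) for sp in labels},
        fst=fst(gm),
        dxy_per_site=dxy(gm, gene_length),
        class_counts=counts,
    )
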