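"""Codon-level selection statistics.

Implements equal-weight (Nei–Gojobori style) counting of synonymous and
nonsynonymous sites and differences with Jukes–Cantor correction, pairwise
dN/dS, McDonald–Kreitman count tallies and the pooled alpha statistic

    alpha = 1 - (D_S * P_N) / (D_N * P_S),

a label-permutation test for the difference in pooled alpha between two gene
classes, and the bounded nonsynonymous fraction f_N = dN / (dN + dS) with its
between-minus-within contrast (DiS) and regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .codons import (
    CODON_TO_AA,
    SITES_BY_CODON,
    STOP_CODONS,
    pathway_counts,
)

__all__ = [
    "PairwiseDnDs",
    "McKCounts",
    "FnResult",
    "count_sites",
    "pairwise_dnds",
    "classify_coding_snp",
    "alpha",
    "alpha_permutation_test",
    "f_n",
    "f_n_contrast",
    "fn_regression",
    "mk_counts_for_gene",
    "pool_counts",
]


@dataclass
class PairwiseDnDs:
    """Counting-method summary of one pairwise coding comparison."""

    gene_id: str
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons: int
    flags: list[str] = field(default_factory=list)


@dataclass
class McKCounts:
    """Fixed-divergence and polymorphism tallies for the MK framework."""

    gene_id: str
    D_N: float
    D_S: float
    P_N: float
    P_S: float

    def __post_init__(self) -> None:
        if min(self.D_N, self.D_S, self.P_N, self.P_S) < 0:
            raise ValueError("MK counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.D_N, self.D_S, self.P_N, self.P_S], dtype=float)


@dataclass
class FnResult:
    gene_id: str
    fN_within: float | None
    fN_between: float | None
    DiS: float | None


def count_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for a sense codon.

    Raises ``ValueError`` on a stop codon.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    return SITES_BY_CODON[codon]


def _check_coding(seq: str, name: str) -> str:
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"{name}: length {len(seq)} not a multiple of 3")
    return seq


def _jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - 4p/3); None when the proportion saturates (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(a: str, b: str, gene_id: str = "") -> PairwiseDnDs:
    """Pairwise dN/dS by equal-weight counting with Jukes–Cantor correction.

    Site totals are averaged over the two sequences; codons with multiple
    differences are resolved by equal-weight averaging over all minimal
    substitution pathways (pathways through stop codons excluded). Codons
    containing N or a stop in either sequence are skipped and flagged.
    """
    a = _check_coding(a, "a")
    b = _check_coding(b, "b")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    flags: list[str] = []
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca not in SITES_BY_CODON or cb not in SITES_BY_CODON:
            flags.append(f"codon {i // 3}: skipped ({ca}/{cb})")
            continue
        n_codons += 1
        sa, na = SITES_BY_CODON[ca]
        sb, nb = SITES_BY_CODON[cb]
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        syn, nonsyn = pathway_counts(ca, cb)
        Sd += syn
        Nd += nonsyn
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    if dS is None:
        flags.append("pS >= 3/4: dS undefined")
    if dN is None:
        flags.append("pN >= 3/4: dN undefined")
    omega = None
    if dN is not None and dS is not None and dS > 0:
        omega = dN / dS
    return PairwiseDnDs(
        gene_id=gene_id,
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=Sd,
        nonsyn_diffs=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        n_codons=n_codons,
    )


def classify_coding_snp(
    codon: str, within_pos: int, ref: str, alt: str
) -> str:
    """Label a coding SNP ``synonymous`` or ``nonsynonymous``.

    ``codon`` is the codon context carrying the reference allele at
    ``within_pos`` (0..2). A variant creating a stop is labelled
    nonsynonymous (with a warning); the MK framework has no stop class.
    """
    codon = codon.upper()
    if codon[within_pos] != ref.upper():
        raise ValueError(
            f"reference allele {ref} does not match codon {codon} at {within_pos}"
        )
    mutated = codon[:within_pos] + alt.upper() + codon[within_pos + 1 :]
    if mutated in STOP_CODONS:
        warnings.warn(
            f"variant {codon}->{mutated} creates a stop codon; counted nonsynonymous",
            stacklevel=2,
        )
        return "nonsynonymous"
    if codon in STOP_CODONS:
        raise ValueError(f"reference codon {codon} is a stop")
    return (
        "synonymous" if CODON_TO_AA[codon] == CODON_TO_AA[mutated] else "nonsynonymous"
    )


def mk_counts_for_gene(
    consensus_a: str,
    consensus_b: str,
    polymorphisms: Iterable[tuple[int, str, str]] = (),
    gene_id: str = "",
) -> McKCounts:
    """MK tallies for one gene.

    Fixed differences (D_N, D_S) come from pathway counting between the two
    species consensus sequences; polymorphisms are ``(pos0, ref, alt)``
    tuples (0-based position within the ORF) classified in the consensus-A
    codon context. Multi-difference codons are decomposed by equal-weight
    pathway averaging; a warning lists them.
    """
    res = pairwise_dnds(consensus_a, consensus_b, gene_id=gene_id)
    a = consensus_a.upper()
    multi = [
        i // 3
        for i in range(0, len(a), 3)
        if sum(x != y for x, y in zip(a[i : i + 3], consensus_b[i : i + 3].upper())) > 1
    ]
    if multi:
        warnings.warn(
            f"{gene_id or 'gene'}: codons with multiple fixed differences "
            f"decomposed by pathway averaging: {multi}",
            stacklevel=2,
        )
    P_N = P_S = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pos, ref, alt in polymorphisms:
            codon_idx = pos // 3
            codon = a[3 * codon_idx : 3 * codon_idx + 3]
            label = classify_coding_snp(codon, pos % 3, ref, alt)
            if label == "synonymous":
                P_S += 1
            else:
                P_N += 1
    return McKCounts(
        gene_id=gene_id, D_N=res.nonsyn_diffs, D_S=res.syn_diffs, P_N=P_N, P_S=P_S
    )


def pool_counts(counts: Sequence[McKCounts], gene_id: str = "pooled") -> McKCounts:
    arr = np.sum([c.as_array() for c in counts], axis=0)
    return McKCounts(gene_id, *arr)


def alpha(c: McKCounts) -> float:
    """Pooled MK alpha: 1 - (D_S * P_N) / (D_N * P_S).

    Undefined (ValueError) when D_N = 0 or P_S = 0.
    """
    if c.D_N <= 0 or c.P_S <= 0:
        raise ValueError(
            f"alpha undefined for D_N={c.D_N}, P_S={c.P_S} (division by zero)"
        )
    return 1.0 - (c.D_S * c.P_N) / (c.D_N * c.P_S)


def _pooled_alpha_matrix(counts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized pooled-alpha difference for many label permutations.

    ``counts`` is (G, 4) columns (D_N, D_S, P_N, P_S); ``labels`` is
    (R, G) boolean, True = class A. Returns (R,) of alpha_A - alpha_B with
    NaN where either pooled alpha is undefined.
    """
    lab = labels.astype(float)
    pooled_a = lab @ counts          # (R, 4)
    pooled_b = (1.0 - lab) @ counts
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = 1.0 - (pooled_a[:, 1] * pooled_a[:, 2]) / (
            pooled_a[:, 0] * pooled_a[:, 3]
        )
        alpha_b = 1.0 - (pooled_b[:, 1] * pooled_b[:, 2]) / (
            pooled_b[:, 0] * pooled_b[:, 3]
        )
    bad = (
        (pooled_a[:, 0] <= 0)
        | (pooled_a[:, 3] <= 0)
        | (pooled_b[:, 0] <= 0)
        | (pooled_b[:, 3] <= 0)
    )
    out = alpha_a - alpha_b
    out[bad] = np.nan
    return out


@dataclass
class PermutationResult:
    delta_alpha: float
    p_value: float
    n_perm: int
    n_redrawn: int
    alpha_a: float
    alpha_b: float


def alpha_permutation_test(
    counts: Sequence[McKCounts],
    in_class_a: Sequence[bool],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """One-sided permutation test for pooled alpha_A > alpha_B.

    Gene class labels are permuted ``n_perm`` times; the one-sided p-value is
    (1 + #{delta_perm >= delta_obs}) / (n_perm + 1). Permutations whose pooled
    counts leave alpha undefined are redrawn (their number is reported).
    """
    labels = np.asarray(in_class_a, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both gene classes must be non-empty")
    mat = np.array([c.as_array() for c in counts], dtype=float)
    if len(mat) != len(labels):
        raise ValueError("counts and labels differ in length")
    obs = _pooled_alpha_matrix(mat, labels[None, :])[0]
    if np.isnan(obs):
        raise ValueError("pooled alpha undefined in the observed partition")
    pooled_a = pool_counts([c for c, l in zip(counts, labels) if l])
    pooled_b = pool_counts([c for c, l in zip(counts, labels) if not l])
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_a = int(labels.sum())
    n_genes = len(labels)
    deltas = np.empty(n_perm)
    filled = 0
    n_redrawn = 0
    while filled < n_perm:
        batch = min(n_perm - filled, 4096)
        perm = np.zeros((batch, n_genes), dtype=bool)
        # vectorized draw of `batch` random n_a-subsets
        keys = rng.random((batch, n_genes))
        idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        np.put_along_axis(perm, idx, True, axis=1)
        d = _pooled_alpha_matrix(mat, perm)
        ok = ~np.isnan(d)
        n_redrawn += int((~ok).sum())
        take = d[ok][: n_perm - filled]
        deltas[filled : filled + len(take)] = take
        filled += len(take)
    p = (1.0 + float(np.sum(deltas >= obs))) / (n_perm + 1.0)
    return PermutationResult(
        delta_alpha=float(obs),
        p_value=p,
        n_perm=n_perm,
        n_redrawn=n_redrawn,
        alpha_a=alpha(pooled_a),
        alpha_b=alpha(pooled_b),
    )


def f_n(dN: float, dS: float) -> float:
    """Bounded nonsynonymous fraction dN / (dN + dS); requires dN + dS > 0."""
    if dN < 0 or dS < 0:
        raise ValueError("rates must be non-negative")
    if dN + dS == 0:
        raise ValueError("f_N undefined when dN + dS = 0")
    return dN / (dN + dS)


def _mean_rates(pairs: Sequence[PairwiseDnDs]) -> tuple[float, float]:
    ds = [p.dS for p in pairs if p.dS is not None and p.dN is not None]
    dn = [p.dN for p in pairs if p.dS is not None and p.dN is not None]
    if not ds:
        raise ValueError("no usable pairs")
    return float(np.mean(dn)), float(np.mean(ds))


def f_n_contrast(
    gene_id: str,
    within_pairs: Sequence[PairwiseDnDs],
    between_pairs: Sequence[PairwiseDnDs],
) -> FnResult:
    """f_N within, f_N between and DiS = f_N-between - f_N-within for a gene.

    dN and dS are averaged over each pair set first (average-then-ratio);
    within-species pairs from both species are pooled into one set. A gene
    where a pair set is entirely invariant (dN + dS = 0) gets None for that
    f_N and for DiS.
    """
    if not within_pairs or not between_pairs:
        raise ValueError("need at least one within pair and one between pair")

    def _fn(pairs: Sequence[PairwiseDnDs]) -> float | None:
        try:
            dn, ds = _mean_rates(pairs)
            return f_n(dn, ds)
        except ValueError:
            return None

    fw = _fn(within_pairs)
    fb = _fn(between_pairs)
    dis = (fb - fw) if (fw is not None and fb is not None) else None
    return FnResult(gene_id=gene_id, fN_within=fw, fN_between=fb, DiS=dis)


def fn_regression(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS of f_N-between on f_N-within: returns (intercept, slope, R^2)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in f_N-within")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(intercept), float(slope), r2
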