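"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's counting code paths: translation goes
through Biopython, site fractions and pathway steps are enumerated directly,
and diversity statistics are recomputed from explicitly enumerated allele
pairs.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """Enumerate all 9 single-base changes; synonymous fraction per position."""
    syn = 0.0
    for pos, b in itertools.product(range(3), BASES):
        if b == codon[pos]:
            continue
        mutant = codon[:pos] + b + codon[pos + 1 :]
        if aa(mutant) == aa(codon):
            syn += 1.0
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_pathway(a: str, b: str) -> tuple[float, float]:
    """Equal-weight average of syn/nonsyn steps over stop-free minimal paths."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    all_paths, stopfree = [], []
    for order in itertools.permutations(diffs):
        cur, s, n, stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if aa(nxt) == aa(cur):
                s += 1
            else:
                n += 1
            if aa(nxt) == "*" and nxt != b:
                stop = True
            cur = nxt
        all_paths.append((s, n))
        if not stop:
            stopfree.append((s, n))
    use = stopfree or all_paths
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


def oracle_pairwise(seq_a: str, seq_b: str) -> dict:
    """Full pairwise counting oracle with Jukes–Cantor correction."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        for c in (ca, cb):
            s, n = oracle_codon_sites(c)
            S += s / 2.0
            N += n / 2.0
        s, n = oracle_pathway(ca, cb)
        Sd += s
        Nd += n
    pS, pN = Sd / S if S else 0.0, Nd / N if N else 0.0

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "dS": jc(pS), "dN": jc(pN)}


def oracle_pi_total(dosage_matrix: np.ndarray) -> float:
    """Mean pairwise differences from explicitly enumerated allele pairs.

    Rows are sites, columns diploid individuals with dosages 0/1/2 (-1
    missing). Per site, alleles are expanded and all unordered pairs
    compared.
    """
    total = 0.0
    for row in dosage_matrix:
        alleles = []
        for d in row:
            if d < 0:
                continue
            alleles += [1] * int(d) + [0] * (2 - int(d))
        n = len(alleles)
        if n < 2:
            continue
        diff = sum(
            1 for i, j in itertools.combinations(range(n), 2) if alleles[i] != alleles[j]
        )
        total += diff / comb(n, 2)
    return total


def oracle_dxy(dosages_a: np.ndarray, dosages_b: np.ndarray, length: int) -> float:
    """Mean inter-population mismatch over enumerated allele cross-pairs."""
    total = 0.0
    for ra, rb in zip(dosages_a, dosages_b):
        al_a = [x for d in ra if d >= 0 for x in [1] * int(d) + [0] * (2 - int(d))]
        al_b = [x for d in rb if d >= 0 for x in [1] * int(d) + [0] * (2 - int(d))]
        if not al_a or not al_b:
            continue
        diff = sum(1 for x in al_a for y in al_b if x != y)
        total += diff / (len(al_a) * len(al_b))
    return total / length


def oracle_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


def random_codon(rng: np.random.Generator, sense_only: bool = True) -> str:
    while True:
        c = "".join(rng.choice(list(BASES), size=3))
        if not sense_only or aa(c) != "*":
            return c
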