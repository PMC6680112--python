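"""Standard genetic code helpers shared by the simulator and the selection statistics.

The translation table is taken from Biopython's standard codon table; everything
derived from it (sense codons, per-codon synonymous site fractions) is computed
once at import time.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (one-letter), stop codons map to "*"
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; ``*`` for a stop."""
    return CODON_TO_AA[codon.upper()]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def single_base_neighbors(codon: str, position: int) -> list[str]:
    """The three codons reachable by changing one base at ``position``."""
    codon = codon.upper()
    return [
        codon[:position] + b + codon[position + 1 :]
        for b in BASES
        if b != codon[position]
    ]


def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each of the three positions contributes ``(# synonymous single-base
    changes)/3`` synonymous sites; changes to stop codons count as
    nonsynonymous. Totals sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for neigh in single_base_neighbors(codon, pos):
            if CODON_TO_AA[neigh] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


#: precomputed (syn_sites, nonsyn_sites) for every sense codon
SITES_BY_CODON: dict[str, tuple[float, float]] = {
    c: codon_sites(c) for c in SENSE_CODONS
}


def diff_positions(a: str, b: str) -> tuple[int, ...]:
    return tuple(i for i in range(3) if a[i] != b[i])


def pathway_counts(a: str, b: str, skip_stop_pathways: bool = True) -> tuple[float, float]:
    """Synonymous/nonsynonymous step counts between two codons.

    All minimal single-substitution pathways from ``a`` to ``b`` are
    enumerated (1, 2 or 6 orderings for 1, 2 or 3 differing positions); each
    step is classified by amino-acid identity of the two intermediate codons
    and the per-pathway counts are averaged with equal weights. Pathways
    passing through a stop codon are excluded unless every pathway does.
    """
    a, b = a.upper(), b.upper()
    diffs = diff_positions(a, b)
    if not diffs:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    stopfree: list[tuple[float, float]] = []
    for order in itertools.permutations(diffs):
        cur = a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            if nxt in STOP_CODONS and nxt != b:
                through_stop = True
            cur = nxt
        pathways.append((syn, nonsyn))
        if not through_stop:
            stopfree.append((syn, nonsyn))
    use = stopfree if (skip_stop_pathways and stopfree) else pathways
    syn = sum(p[0] for p in use) / len(use)
    nonsyn = sum(p[1] for p in use) / len(use)
    return syn, nonsyn
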