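"""GO over-representation analysis and dual-category pleiotropy screens.

The ORA is a hypergeometric upper-tail test of each GO term in a study set
against a background, restricted to terms of intermediate size (10–100 genes
by default) with Benjamini–Hochberg FDR. The pleiotropy screens look for
genes carrying at least one ecological-stress and one reproductive focal
annotation, reached either through positive selection (omega > 1) or through
non-overlapping differential expression (NODE).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GoMap",
    "FocalTermSets",
    "CandidateReport",
    "go_ora",
    "pleiotropy_screen_selection",
    "pleiotropy_screen_expression",
    "two_proportion_ztest",
]

_TERM_RE = re.compile(r"^GO:\d{7}$")

#: default focal terms: ecological-stress responses and reproduction
ECOLOGICAL_TERMS = frozenset(
    {"GO:0006950", "GO:0006970", "GO:0009414", "GO:0010038"}
)
REPRODUCTIVE_TERMS = frozenset({"GO:0000003", "GO:0009909"})


@dataclass
class FocalTermSets:
    ecological: frozenset = ECOLOGICAL_TERMS
    reproductive: frozenset = REPRODUCTIVE_TERMS

    def __post_init__(self) -> None:
        self.ecological = frozenset(self.ecological)
        self.reproductive = frozenset(self.reproductive)
        if self.ecological & self.reproductive:
            raise ValueError("focal term sets must be disjoint")


class GoMap:
    """Gene -> GO term mapping with the inverse term -> gene view."""

    def __init__(
        self,
        gene_to_terms: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.gene_to_terms: dict[str, frozenset] = {}
        self.term_to_genes: dict[str, set] = {}
        for gene, terms in gene_to_terms.items():
            tset = frozenset(terms)
            for t in tset:
                if not _TERM_RE.match(t):
                    raise ValueError(f"malformed GO term id {t!r} for gene {gene}")
                self.term_to_genes.setdefault(t, set()).add(gene)
            self.gene_to_terms[gene] = tset
        self.descriptions = dict(descriptions or {})

    def terms_of(self, gene: str) -> frozenset:
        return self.gene_to_terms.get(gene, frozenset())

    def annotated_genes(self) -> set:
        return {g for g, t in self.gene_to_terms.items() if t}

    @classmethod
    def from_tsv(cls, path: str) -> "GoMap":
        """gene_id<TAB>comma-separated GO ids (empty second field allowed)."""
        mapping: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                gene = parts[0]
                terms = [t for t in parts[1].split(",") if t] if len(parts) > 1 else []
                mapping[gene] = terms
        return cls(mapping)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.gene_to_terms):
                fh.write(f"{gene}\t{','.join(sorted(self.gene_to_terms[gene]))}\n")


@dataclass
class CandidateReport:
    gene_id: str
    evidence: str  # "positive_selection" or "NODE"
    tissues: tuple = ()
    ecological_terms: frozenset = frozenset()
    reproductive_terms: frozenset = frozenset()
    verdict: bool = False
    notes: str = ""


def go_ora(
    study: Iterable[str],
    background: Iterable[str],
    go_map: GoMap,
    min_term: int = 10,
    max_term: int = 100,
    annotated_only: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of GO terms in ``study``.

    Terms annotating fewer than ``min_term`` or more than ``max_term``
    background genes are excluded before testing. ``annotated_only``
    restricts the background to genes carrying at least one term (the
    conventional ORA universe). Columns: term, description, K (term genes in
    background), k (term genes in study), p, fdr.
    """
    background = set(background)
    if annotated_only:
        background &= go_map.annotated_genes()
    study = set(study) & background if annotated_only else set(study)
    if not set(study) <= background:
        raise ValueError("study set must be a subset of the background")
    rows = []
    N, n = len(background), len(study)
    for term, genes in sorted(go_map.term_to_genes.items()):
        K = len(genes & background)
        if K < min_term or K > max_term:
            continue
        k = len(genes & study)
        # upper tail P(X >= k); k = 0 gives p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "description": go_map.descriptions.get(term, ""),
                "K": K,
                "k": k,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "description", "K", "k", "p"])
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df


def _dual_terms(gene: str, go_map: GoMap, focal: FocalTermSets):
    terms = go_map.terms_of(gene)
    return terms & focal.ecological, terms & focal.reproductive


def pleiotropy_screen_selection(
    omega_by_gene: Mapping[str, float | None],
    go_map: GoMap,
    focal: FocalTermSets | None = None,
) -> list[CandidateReport]:
    """Positive-selection route: omega > 1 plus dual eco/repro annotation."""
    focal = focal or FocalTermSets()
    out = []
    for gene in sorted(omega_by_gene):
        omega = omega_by_gene[gene]
        if omega is None or omega <= 1.0:
            continue
        eco, rep = _dual_terms(gene, go_map, focal)
        out.append(
            CandidateReport(
                gene_id=gene,
                evidence="positive_selection",
                ecological_terms=eco,
                reproductive_terms=rep,
                verdict=bool(eco and rep),
                notes=f"omega={omega:.3g}",
            )
        )
    return [c for c in out if c.verdict] + [c for c in out if not c.verdict]


def pleiotropy_screen_expression(
    node_genes: Mapping[str, Sequence[str]],
    go_map: GoMap,
    focal: FocalTermSets | None = None,
) -> tuple[list[CandidateReport], list[CandidateReport]]:
    """NODE route: primary = dual-category; secondary = >=2 ecological, no
    reproductive term.

    ``node_genes`` maps gene id -> tissues in which it is NODE.
    """
    focal = focal or FocalTermSets()
    primary, secondary = [], []
    for gene in sorted(node_genes):
        eco, rep = _dual_terms(gene, go_map, focal)
        report = CandidateReport(
            gene_id=gene,
            evidence="NODE",
            tissues=tuple(node_genes[gene]),
            ecological_terms=eco,
            reproductive_terms=rep,
        )
        if eco and rep:
            report.verdict = True
            primary.append(report)
        elif len(eco) >= 2 and not rep:
            report.notes = "ecological-only secondary candidate"
            secondary.append(report)
    return primary, secondary


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test, two-sided normal p."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        import warnings

        warnings.warn("degenerate pooled proportion; p set to 1", stacklevel=2)
        return 0.0, 1.0
    se = (pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)) ** 0.5
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))
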