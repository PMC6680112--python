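"""Count normalization, low-expression filtering, DE calling and NODE detection.

Counts are normalized to reads per million mapped reads (rpm). Per tissue, a
gene must reach rpm >= 1 in every sample to enter testing. The built-in DE
engine fits an ordinary linear model to log2(rpm + 0.5) with species and
collection-trip (batch) effects and tests the species coefficient; external
callers can supply (gene, logFC, p) tables instead. Benjamini–Hochberg FDR is
applied within each tissue, and NODE (non-overlapping differential
expression) flags significant genes whose per-sample rpm ranges in the two
species do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "rpm",
    "low_expression_filter",
    "de_test",
    "de_from_table",
    "node_detect",
    "soil_contrasts",
]

TISSUES = ("leaf", "floral", "root")
META_COLUMNS = ("sample_id", "species", "tissue", "soil", "trip")


def _check_meta(meta: pd.DataFrame, columns) -> None:
    missing = set(columns) - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")


def rpm(counts: pd.DataFrame, library_totals: pd.Series) -> pd.DataFrame:
    """counts * 1e6 / per-sample mapped-read total."""
    totals = library_totals.reindex(counts.columns)
    if totals.isna().any():
        raise ValueError("library totals missing for some samples")
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts * 1e6 / totals


def low_expression_filter(
    rpm_matrix: pd.DataFrame, meta: pd.DataFrame, tissue: str, threshold: float = 1.0
) -> pd.Index:
    """Genes with rpm >= threshold in *every* sample of the tissue."""
    samples = meta.loc[meta["tissue"] == tissue, "sample_id"]
    if len(samples) == 0:
        raise ValueError(f"no samples for tissue {tissue!r}")
    sub = rpm_matrix[list(samples)]
    return sub.index[(sub >= threshold).all(axis=1)]


@dataclass
class DEResult:
    """Per-tissue differential-expression table.

    ``table`` columns: gene_id, log2fc (species A over B), p, fdr,
    significant, node, direction (species label the gene is up in, or "").
    """

    tissue: str
    table: pd.DataFrame
    species_labels: tuple[str, str]


def _design_matrix(meta_t: pd.DataFrame, species_labels, use_trip: bool) -> np.ndarray:
    cols = [np.ones(len(meta_t)), (meta_t["species"] == species_labels[0]).astype(float)]
    if use_trip:
        trips = sorted(meta_t["trip"].unique())
        for t in trips[1:]:
            cols.append((meta_t["trip"] == t).astype(float).to_numpy())
    return np.column_stack(cols)


def de_test(
    counts: pd.DataFrame,
    library_totals: pd.Series,
    meta: pd.DataFrame,
    tissue: str,
    alpha: float = 0.05,
    rpm_threshold: float = 1.0,
) -> DEResult:
    """Built-in DE engine for one tissue.

    Per retained gene, OLS of log2(rpm + 0.5) on species plus trip factors;
    the species-effect t statistic gives the p-value. When species and trip
    are perfectly confounded the trip factor is dropped with a warning.
    Requires >= 2 samples per species in the tissue.
    """
    _check_meta(meta, META_COLUMNS)
    meta_t = meta[meta["tissue"] == tissue].copy()
    species_labels = tuple(sorted(meta_t["species"].unique()))
    if len(species_labels) != 2:
        raise ValueError(f"tissue {tissue!r} needs exactly two species")
    for sp in species_labels:
        if (meta_t["species"] == sp).sum() < 2:
            raise ValueError(f"tissue {tissue!r}: fewer than 2 samples for {sp}")

    rpm_all = rpm(counts, library_totals)
    genes = low_expression_filter(rpm_all, meta, tissue, rpm_threshold)
    samples = list(meta_t["sample_id"])
    y = np.log2(rpm_all.loc[genes, samples].to_numpy(dtype=float) + 0.5)

    use_trip = meta_t["trip"].nunique() > 1
    X = _design_matrix(meta_t, species_labels, use_trip)
    if use_trip and np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            f"tissue {tissue!r}: species and trip confounded; dropping trip factor",
            stacklevel=2,
        )
        X = _design_matrix(meta_t, species_labels, use_trip=False)

    n, k = X.shape
    dof = n - k
    if dof < 1:
        raise ValueError(f"tissue {tissue!r}: no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ xtx_inv.T  # (G, k)
    resid = y - beta @ X.T
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    logfc = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), dof)
    p = np.where(se > 0, p, 1.0)

    table = pd.DataFrame(
        {
            "gene_id": list(genes),
            "log2fc": logfc,
            "p": p,
        }
    )
    return _finish_de(table, tissue, species_labels, alpha)


def de_from_table(
    external: pd.DataFrame,
    tissue: str,
    species_labels: tuple[str, str],
    alpha: float = 0.05,
) -> DEResult:
    """External DE route: (gene_id, log2fc, p) table; same FDR step applied."""
    table = external[["gene_id", "log2fc", "p"]].copy()
    return _finish_de(table, tissue, tuple(species_labels), alpha)


def _finish_de(
    table: pd.DataFrame, tissue: str, species_labels, alpha: float
) -> DEResult:
    if len(table):
        table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["fdr"] = []
    table["significant"] = table["fdr"] < alpha
    table["node"] = False
    table["direction"] = np.where(
        table["significant"],
        np.where(table["log2fc"] > 0, species_labels[0], species_labels[1]),
        "",
    )
    table.loc[table["log2fc"] == 0, "direction"] = ""
    return DEResult(tissue=tissue, table=table.reset_index(drop=True), species_labels=species_labels)


def node_detect(
    rpm_matrix: pd.DataFrame, meta: pd.DataFrame, de: DEResult
) -> DEResult:
    """Flag NODE genes: significant and with disjoint per-species rpm ranges.

    Strict inequality: min(rpm in the up species) > max(rpm in the other).
    The direction column records which species the gene is up in.
    """
    meta_t = meta[meta["tissue"] == de.tissue]
    sp_a, sp_b = de.species_labels
    samples_a = list(meta_t.loc[meta_t["species"] == sp_a, "sample_id"])
    samples_b = list(meta_t.loc[meta_t["species"] == sp_b, "sample_id"])
    tab = de.table
    genes = tab["gene_id"]
    a = rpm_matrix.loc[genes, samples_a].to_numpy(dtype=float)
    b = rpm_matrix.loc[genes, samples_b].to_numpy(dtype=float)
    up_a = a.min(axis=1) > b.max(axis=1)
    up_b = b.min(axis=1) > a.max(axis=1)
    sig = tab["significant"].to_numpy()
    node = sig & (up_a | up_b)
    tab = tab.copy()
    tab["node"] = node
    direction = tab["direction"].to_numpy(dtype=object)
    direction[node & up_a] = sp_a
    direction[node & up_b] = sp_b
    tab["direction"] = direction
    return DEResult(tissue=de.tissue, table=tab, species_labels=de.species_labels)


def soil_contrasts(
    counts: pd.DataFrame,
    library_totals: pd.Series,
    meta: pd.DataFrame,
    tissue: str,
    species_two_soils: str,
    other_species: str,
    soils: tuple[str, str] = ("calcarenite", "volcanic"),
    alpha: float = 0.05,
) -> dict:
    """Three DE contrasts and their overlap partition for one tissue.

    (i) within ``species_two_soils``: soil 1 vs soil 2; (ii) soil-1 samples
    vs ``other_species``; (iii) soil-2 samples vs ``other_species``. Returns
    the three DEResults plus the partition of significant genes from (ii)
    and (iii) into unique/shared sets.
    """
    _check_meta(meta, META_COLUMNS)
    results: dict = {}
    specs = {
        "within_soils": (
            (meta["species"] == species_two_soils) & (meta["soil"] == soils[0]),
            (meta["species"] == species_two_soils) & (meta["soil"] == soils[1]),
            ("soil:" + soils[0], "soil:" + soils[1]),
        ),
        "soil1_vs_other": (
            (meta["species"] == species_two_soils) & (meta["soil"] == soils[0]),
            meta["species"] == other_species,
            (species_two_soils + ":" + soils[0], other_species),
        ),
        "soil2_vs_other": (
            (meta["species"] == species_two_soils) & (meta["soil"] == soils[1]),
            meta["species"] == other_species,
            (species_two_soils + ":" + soils[1], other_species),
        ),
    }
    for name, (mask1, mask2, labels) in specs.items():
        sub = meta[(mask1 | mask2) & (meta["tissue"] == tissue)].copy()
        if mask1[sub.index].sum() < 2 or mask2[sub.index].sum() < 2:
            warnings.warn(f"contrast {name}: too few samples, skipped", stacklevel=2)
            results[name] = None
            continue
        sub = sub.assign(species=np.where(mask1[sub.index], labels[0], labels[1]))
        # relabelled groups ride through the standard two-group engine
        results[name] = de_test(counts, library_totals, sub, tissue, alpha)

    def _sig(res: DEResult | None) -> set:
        if res is None:
            return set()
        t = res.table
        return set(t.loc[t["significant"], "gene_id"])

    sig2, sig3 = _sig(results["soil1_vs_other"]), _sig(results["soil2_vs_other"])
    results["partition"] = {
        "unique_soil1": sig2 - sig3,
        "unique_soil2": sig3 - sig2,
        "shared": sig2 & sig3,
    }
    return results
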