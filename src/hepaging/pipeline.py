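"""End-to-end orchestration: qc -> normalize -> scoring/zonation -> noise ->
DEGs -> overlap modules -> crosstalk -> term network, with a provenance
manifest and deterministic per-stage seeding.

Every stage writes plain TSV outputs into the run directory; rerunning with
the same config and inputs reproduces bit-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .crosstalk import differential_network, permutation_test, read_lr_pairs
from .deg import overlap_modules, shared_degs, signed_external_overlap, wilcoxon_deg
from .io_core import (
    annotate_cell_meta,
    normalize_log1p_cp10k,
    qc_filter,
    read_cell_meta,
    read_counts,
    read_gmt,
    write_cell_meta,
    write_gmt,
)
from .noise import (
    balance_groups,
    default_target_umi,
    downsample_umi,
    noise_correlated_genes,
    noise_ratio,
    transcriptional_noise,
)
from .scoring import GeneSet, identity_drift, module_score, young_identity_sets, zonation_assign
from .termnet import TermSet, build_term_graph

logger = logging.getLogger("hepaging")

__all__ = ["stage_seed", "run_pipeline", "make_report"]

REQUIRED_OUTPUTS = ["qc_report.json", "noise_summary.tsv", "shared_degs.tsv"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed; adding stages never perturbs earlier draws."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, out_dir=None, seed=None) -> Path:
    """Run all configured stages; returns the run directory.

    Optional stages (crosstalk without ``lr_pairs``, term network without
    ``terms``, zonation without a ``zonation`` block) are skipped with a
    logged notice.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "hepaging_run"))
    out.mkdir(parents=True, exist_ok=True)
    global_seed = int(seed if seed is not None else cfg.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": global_seed,
        "stage_seeds": {},
        "parameters": {},
        "inputs": {},
        "outputs": {},
        "skipped": [],
    }

    counts_cfg = cfg["counts"]
    input_paths = {
        "mtx": counts_cfg["mtx"],
        "genes": counts_cfg["genes"],
        "barcodes": counts_cfg["barcodes"],
        "cell_meta": cfg["cell_meta"],
    }
    for key in ("lr_pairs", "external_signature", "terms", "gene_sets"):
        if cfg.get(key):
            input_paths[key] = cfg[key]
    for name, path in input_paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"configured input {name!r} not found: {path}")
        manifest["inputs"][name] = _sha256(path)

    # ---- qc ----
    qc_cfg = dict(min_genes=200, max_pct_mito=0.05, mito_gene_prefix="MT-")
    qc_cfg.update(cfg.get("qc", {}))
    manifest["parameters"]["qc"] = qc_cfg
    cm = read_counts(counts_cfg["mtx"], counts_cfg["genes"], counts_cfg["barcodes"])
    meta = read_cell_meta(cfg["cell_meta"])
    meta = annotate_cell_meta(cm, meta, qc_cfg["mito_gene_prefix"])
    cm, meta, report = qc_filter(cm, meta, **qc_cfg)
    (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    write_cell_meta(meta, out / "cell_meta_filtered.tsv")
    logger.info("qc: %d/%d cells pass", report.n_pass_cells, report.n_input_cells)

    nm = normalize_log1p_cp10k(cm)
    has_cell_type = "cell_type" in meta.columns and meta["cell_type"].notna().any()

    # ---- scoring ----
    score_cfg = dict(n_bins=24, n_ctrl=100, top_n=50, lfc_min=0.5, padj_max=0.05)
    score_cfg.update(cfg.get("score", {}))
    manifest["parameters"]["score"] = score_cfg
    manifest["stage_seeds"]["score"] = stage_seed(global_seed, "score")
    if has_cell_type:
        sets = young_identity_sets(
            nm,
            meta,
            top_n=score_cfg["top_n"],
            lfc_min=score_cfg["lfc_min"],
            padj_max=score_cfg["padj_max"],
        )
        write_gmt({k: v.genes for k, v in sets.items()}, out / "identity_sets.gmt")
        drift = identity_drift(
            nm,
            meta,
            sets,
            n_bins=score_cfg["n_bins"],
            n_ctrl=score_cfg["n_ctrl"],
            seed=stage_seed(global_seed, "score"),
        )
        drift.to_csv(out / "identity_drift.tsv", sep="\t", index=False)
    if cfg.get("gene_sets"):
        gmt = read_gmt(cfg["gene_sets"])
        scores = pd.DataFrame(index=pd.Index(nm.cell_ids, name="cell_id"))
        for name, genes in gmt.items():
            sv = module_score(
                nm,
                GeneSet(name, genes),
                n_bins=score_cfg["n_bins"],
                n_ctrl=score_cfg["n_ctrl"],
                seed=stage_seed(global_seed, f"score:{name}"),
            )
            scores[name] = sv.scores
        scores.reset_index().to_csv(out / "module_scores.tsv", sep="\t", index=False)

    # ---- zonation ----
    zone_labels = None
    zon_cfg = cfg.get("zonation")
    if zon_cfg and has_cell_type:
        marker_sets = read_gmt(zon_cfg["marker_gmt"])
        hep_cells = meta.loc[
            meta["cell_type"] == zon_cfg.get("cell_type", "Hep"), "cell_id"
        ].tolist()
        zone_labels = zonation_assign(
            nm,
            hep_cells,
            GeneSet(zon_cfg.get("pp_set", "PP_markers"), marker_sets[zon_cfg.get("pp_set", "PP_markers")]),
            GeneSet(zon_cfg.get("pc_set", "PC_markers"), marker_sets[zon_cfg.get("pc_set", "PC_markers")]),
            n_bins=score_cfg["n_bins"],
            n_ctrl=score_cfg["n_ctrl"],
            seed=stage_seed(global_seed, "zonation"),
        )
        zone_labels.rename_axis("cell_id").reset_index().to_csv(
            out / "zonation.tsv", sep="\t", index=False
        )
        manifest["parameters"]["zonation"] = zon_cfg
    elif zon_cfg:
        manifest["skipped"].append("zonation (no cell_type labels)")
    else:
        manifest["skipped"].append("zonation (no config block)")
        logger.info("zonation: skipped (no config block)")

    # ---- noise ----
    noise_cfg = dict(target_umi=None, gene_min_pct=0.1, min_cells=20, n_bins=20)
    noise_cfg.update(cfg.get("noise", {}))
    manifest["parameters"]["noise"] = noise_cfg
    manifest["stage_seeds"]["noise"] = stage_seed(global_seed, "noise")
    if has_cell_type:
        balanced = balance_groups(
            meta, seed=stage_seed(global_seed, "noise:balance"), min_cells=noise_cfg["min_cells"]
        )
        cm_bal = cm.subset_cells(balanced)
        target = noise_cfg["target_umi"] or default_target_umi(cm_bal)
        cm_ds = downsample_umi(cm_bal, target, seed=stage_seed(global_seed, "noise:downsample"))
        nt = transcriptional_noise(cm_ds, meta, gene_min_pct=noise_cfg["gene_min_pct"])
        nt.to_csv(out / "noise_table.tsv", sep="\t", index=False)
        summary = noise_ratio(nt)
        summary.to_csv(out / "noise_summary.tsv", sep="\t", index=False)
        if len(nt):
            focus = noise_cfg.get("gene_corr_cell_type") or nt["cell_type"].value_counts().idxmax()
            nm_ds = normalize_log1p_cp10k(cm_ds)
            genes_tbl = noise_correlated_genes(nm_ds, nt, focus)
            genes_tbl.to_csv(out / "noise_genes.tsv", sep="\t", index=False)
            manifest["parameters"]["noise"]["gene_corr_cell_type"] = focus
            manifest["parameters"]["noise"]["target_umi_used"] = int(target)

    # ---- deg ----
    deg_cfg = dict(min_pct=0.1, lfc_prefilter=0.25, k_min=3)
    deg_cfg.update(cfg.get("deg", {}))
    manifest["parameters"]["deg"] = deg_cfg
    deg_tables: dict[str, pd.DataFrame] = {}
    if has_cell_type:
        for ct in sorted(meta["cell_type"].dropna().unique()):
            grp_sizes = meta[meta["cell_type"] == ct]["group"].value_counts()
            if grp_sizes.get("young", 0) < 3 or grp_sizes.get("aged", 0) < 3:
                logger.info("deg: skipping %s (too few cells per group)", ct)
                continue
            table = wilcoxon_deg(
                nm, meta, ct, min_pct=deg_cfg["min_pct"], lfc_prefilter=deg_cfg["lfc_prefilter"]
            )
            table.to_csv(out / f"deg_{ct}.tsv", sep="\t", index=False)
            deg_tables[ct] = table
    if len(deg_tables) >= deg_cfg["k_min"]:
        shared = shared_degs(deg_tables, k_min=deg_cfg["k_min"])
    else:
        shared = pd.DataFrame(columns=["gene", "direction", "cell_types", "k"])
    shared.to_csv(out / "shared_degs.tsv", sep="\t", index=False)

    # ---- zonation overlap modules ----
    if zone_labels is not None:
        zmeta = meta[meta["cell_id"].isin(zone_labels.index)].copy()
        zmeta["cell_type"] = zone_labels.loc[zmeta["cell_id"]].to_numpy()
        subtype_tables = {}
        for zone in ("PP", "MZ", "PC"):
            grp_sizes = zmeta[zmeta["cell_type"] == zone]["group"].value_counts()
            if grp_sizes.get("young", 0) < 3 or grp_sizes.get("aged", 0) < 3:
                logger.info("modules: %s has too few cells per group", zone)
                continue
            subtype_tables[zone] = wilcoxon_deg(
                nm, zmeta, zone, min_pct=deg_cfg["min_pct"], lfc_prefilter=deg_cfg["lfc_prefilter"]
            )
        if len(subtype_tables) == 3:
            modules, discordant = overlap_modules(subtype_tables)
            modules.to_csv(out / "zonation_modules.tsv", sep="\t", index=False)
            discordant.to_csv(out / "discordant.tsv", sep="\t", index=False)
        else:
            manifest["skipped"].append("zonation modules (missing subtype groups)")

    # ---- external signature overlap ----
    if cfg.get("external_signature") and deg_tables:
        external = pd.read_csv(cfg["external_signature"], sep="\t", dtype=str)
        rows = []
        for ct, table in deg_tables.items():
            overlap = signed_external_overlap(table, external)
            for category, genes in overlap.items():
                for gene in sorted(genes):
                    rows.append({"cell_type": ct, "gene": gene, "category": category})
        pd.DataFrame(rows, columns=["cell_type", "gene", "category"]).to_csv(
            out / "external_overlap.tsv", sep="\t", index=False
        )

    # ---- crosstalk ----
    if cfg.get("lr_pairs") and has_cell_type:
        xt_cfg = dict(n_perm=1000)
        xt_cfg.update(cfg.get("crosstalk", {}))
        manifest["parameters"]["crosstalk"] = xt_cfg
        manifest["stage_seeds"]["crosstalk"] = stage_seed(global_seed, "crosstalk")
        pairs = read_lr_pairs(cfg["lr_pairs"])
        records = {}
        for group in ("young", "aged"):
            records[group] = permutation_test(
                nm,
                meta,
                pairs,
                group,
                n_perm=xt_cfg["n_perm"],
                seed=stage_seed(global_seed, f"crosstalk:{group}"),
            )
            records[group].to_csv(out / f"interactions_{group}.tsv", sep="\t", index=False)
        diff, aged_spec, young_spec = differential_network(records["young"], records["aged"])
        diff.to_csv(out / "diff_edges.tsv", sep="\t", index=False)
        aged_spec.to_csv(out / "aged_specific_interactions.tsv", sep="\t", index=False)
        young_spec.to_csv(out / "young_specific_interactions.tsv", sep="\t", index=False)
    else:
        manifest["skipped"].append("crosstalk (no lr_pairs configured)")
        logger.info("crosstalk: skipped (no lr_pairs configured)")

    # ---- term network ----
    if cfg.get("terms"):
        tn_cfg = dict(kappa_threshold=0.3)
        tn_cfg.update(cfg.get("termnet", {}))
        manifest["parameters"]["termnet"] = tn_cfg
        term_sets = [TermSet(name, set(genes)) for name, genes in read_gmt(cfg["terms"]).items()]
        if len(term_sets) >= 2:
            graph = build_term_graph(term_sets, threshold=tn_cfg["kappa_threshold"])
            edges = pd.DataFrame(
                [
                    {"term_a": a, "term_b": b, "kappa": d["kappa"]}
                    for a, b, d in sorted(graph.edges(data=True))
                ],
                columns=["term_a", "term_b", "kappa"],
            )
            edges.to_csv(out / "term_edges.tsv", sep="\t", index=False)
            nx.write_graphml(graph, out / "term_graph.graphml")
    else:
        manifest["skipped"].append("termnet (no terms configured)")

    for path in sorted(out.glob("*")):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def make_report(run_dir) -> dict[str, pd.DataFrame]:
    """Summary tables aggregated from a completed run directory."""
    run = Path(run_dir)
    missing = [name for name in REQUIRED_OUTPUTS if not (run / name).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages/outputs: {missing}")
    report: dict[str, pd.DataFrame] = {}

    report["noise_ratios"] = pd.read_csv(run / "noise_summary.tsv", sep="\t")

    deg_rows = []
    for path in sorted(run.glob("deg_*.tsv")):
        table = pd.read_csv(path, sep="\t")
        sig = (
            table.loc[table["significant"].astype(bool)]
            if "significant" in table
            else table.iloc[0:0]
        )
        deg_rows.append(
            {
                "cell_type": path.stem.removeprefix("deg_"),
                "n_deg": len(sig),
                "n_up": int((sig["direction"] == "up").sum()) if len(sig) else 0,
                "n_down": int((sig["direction"] == "down").sum()) if len(sig) else 0,
            }
        )
    report["deg_counts"] = pd.DataFrame(deg_rows, columns=["cell_type", "n_deg", "n_up", "n_down"])

    modules_path = run / "zonation_modules.tsv"
    if modules_path.exists():
        modules = pd.read_csv(modules_path, sep="\t")
        if len(modules):
            counts = (
                modules.groupby(["module_id", "direction", "subtypes"])
                .size()
                .reset_index(name="n_genes")
                .sort_values("module_id")
                .reset_index(drop=True)
            )
        else:
            counts = pd.DataFrame(columns=["module_id", "direction", "subtypes", "n_genes"])
        report["module_counts"] = counts

    diff_path = run / "diff_edges.tsv"
    if diff_path.exists():
        report["diff_edges"] = pd.read_csv(diff_path, sep="\t")

    for name, frame in report.items():
        frame.to_csv(run / f"report_{name}.tsv", sep="\t", index=False)
    return report
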