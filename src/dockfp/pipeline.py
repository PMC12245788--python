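"""Stage orchestration shared by the CLI and programmatic callers.

Each stage reads plain-text inputs, writes its artifacts under an output
directory and returns a manifest dictionary (inputs, parameters, seed, row
counts, output files) sufficient to re-execute the run.  Manifests contain
no timestamps, so repeated runs on identical inputs produce byte-identical
tabular/JSON outputs (images are exempt from that guarantee).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ingest import ScoreMatrix, aggregate_best, read_chain_map, read_docking_records
from .fingerprint import (FingerprintSet, hit_table, heatmap_export,
                          select_top_targets, zscore_fingerprints)
from .cluster import (cut_tree, dendrogram_export, fingerprint_rmsd,
                      newick_export, ward_linkage)
from .enrich import evaluate_ligand, read_actives, EnrichError
from .synthetic import SyntheticConfig, generate, write_fixture

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Bundled inputs and parameters for a pipeline run.

    Defaults encode the method's standard choices: top-10 target union,
    hit cutoff Z < -2.58 with at least 3 ligands, BEDROC/RIE alpha = 20,
    EF at the top 10 %, pChEMBL > 4 actives.
    """

    scores: str | None = None
    chain_map: str | None = None
    actives: str | None = None
    exclude: list[str] = field(default_factory=list)
    include: list[str] = field(default_factory=list)
    out: str = "dockfp_out"
    top_k: int = 10
    z_cut: float = -2.58
    min_ligands: int = 3
    alpha: float = 20.0
    ef_fractions: list[float] = field(default_factory=lambda: [0.10])
    tg_bins: int = 10
    pchembl_min: float = 4.0
    cut_k: int | None = 2
    cut_height: float | None = None
    seed: int = 0


def _write_manifest(out: Path, manifest: dict) -> Path:
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_simulate(cfg: RunConfig, synth: SyntheticConfig | None = None) -> dict:
    """Generate a synthetic fixture (scores, chain map, actives, truth)."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    synth = synth or SyntheticConfig(seed=cfg.seed)
    records, cmap, truth = generate(synth)
    paths = write_fixture(records, cmap, truth, out)
    manifest = {
        "stage": "simulate",
        "version": __version__,
        "seed": synth.seed,
        "parameters": dataclasses.asdict(synth),
        "counts": {"records": len(records), "chains": len(cmap),
                   "actives": len(truth.actives)},
        "outputs": {k: str(p) for k, p in paths.items()},
    }
    _write_manifest(out, manifest)
    return manifest


def run_aggregate(cfg: RunConfig) -> tuple[ScoreMatrix, dict]:
    """Read scores + chain map and write the best-score matrix."""
    if not cfg.scores or not cfg.chain_map:
        raise ValueError("aggregate needs --scores and --chain-map")
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    report = read_docking_records(cfg.scores)
    cmap = read_chain_map(cfg.chain_map)
    matrix = aggregate_best(report.records, cmap)
    matrix.to_csv(out / "score_matrix.csv")
    matrix.provenance_to_csv(out / "provenance.csv")
    manifest = {
        "stage": "aggregate",
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {"scores": cfg.scores, "chain_map": cfg.chain_map},
        "counts": {
            "rows": report.n_rows,
            "rejected_rows": report.n_rejected,
            "unmapped_records": matrix.n_unmapped,
            "used_records": matrix.n_used,
            "ligands": len(matrix.ligands),
            "targets": len(matrix.targets),
        },
        "outputs": {"score_matrix": str(out / "score_matrix.csv"),
                    "provenance": str(out / "provenance.csv")},
    }
    _write_manifest(out, manifest)
    return matrix, manifest


def run_fingerprint(cfg: RunConfig, matrix: ScoreMatrix | None = None,
                    target_classes: dict[str, str] | None = None
                    ) -> tuple[FingerprintSet, dict]:
    """Z-score fingerprints, curated top-target list, hit table, heatmap."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        if not cfg.scores:
            raise ValueError("fingerprint needs --scores (aggregated matrix CSV)")
        matrix = ScoreMatrix.from_csv(cfg.scores)
    fps = zscore_fingerprints(matrix)
    fps.to_csv(out / "fingerprints.csv")
    top = select_top_targets(fps, k=cfg.top_k, exclude=cfg.exclude,
                             include=cfg.include)
    pd.DataFrame({"uniprot_id": top}).to_csv(out / "top_targets.csv", index=False)
    hits = hit_table(fps, z_cut=cfg.z_cut, min_ligands=cfg.min_ligands)
    hits.to_csv(out / "hit_table.csv", index=False)
    heatmap_export(fps, top, out / "heatmap.png", out / "heatmap_long.csv",
                   target_classes=target_classes)
    manifest = {
        "stage": "fingerprint",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {"top_k": cfg.top_k, "z_cut": cfg.z_cut,
                       "min_ligands": cfg.min_ligands,
                       "exclude": list(cfg.exclude), "include": list(cfg.include)},
        "counts": {"ligands": len(fps.ligands), "targets": fps.n_targets,
                   "dropped_targets": fps.n_dropped_targets,
                   "top_targets": len(top), "hit_targets": len(hits)},
        "outputs": {k: str(out / v) for k, v in {
            "fingerprints": "fingerprints.csv",
            "top_targets": "top_targets.csv",
            "hit_table": "hit_table.csv",
            "heatmap": "heatmap.png",
            "heatmap_long": "heatmap_long.csv"}.items()},
    }
    _write_manifest(out, manifest)
    return fps, manifest


def run_cluster(cfg: RunConfig, fps: FingerprintSet | None = None
                ) -> tuple[pd.Series, dict]:
    """Fingerprint RMSD matrix, Ward dendrogram, Newick/linkage exports, cut."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    if fps is None:
        if not cfg.scores:
            raise ValueError("cluster needs --scores (fingerprint CSV)")
        Z = pd.read_csv(cfg.scores, index_col="ligand_id")
        Z.index = Z.index.astype(str)
        fps = FingerprintSet(Z=Z, mu=Z.mean(axis=1), sigma=Z.std(axis=1, ddof=1))
    dm = fingerprint_rmsd(fps)
    dm.to_csv(out / "distance_matrix.csv")
    tree = ward_linkage(dm)
    tree.to_csv(out / "linkage.csv")
    newick_export(tree, out / "tree.nwk")
    dendrogram_export(tree, out / "dendrogram.png")
    labels = cut_tree(tree, height=cfg.cut_height,
                      k=cfg.cut_k if cfg.cut_height is None else None)
    labels.rename_axis("ligand_id").to_csv(out / "clusters.csv")
    manifest = {
        "stage": "cluster",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {"cut_k": cfg.cut_k, "cut_height": cfg.cut_height},
        "counts": {"ligands": len(dm.ligands), "targets": dm.n_targets,
                   "clusters": int(labels.nunique())},
        "outputs": {k: str(out / v) for k, v in {
            "distance_matrix": "distance_matrix.csv",
            "linkage": "linkage.csv",
            "newick": "tree.nwk",
            "dendrogram": "dendrogram.png",
            "clusters": "clusters.csv"}.items()},
    }
    _write_manifest(out, manifest)
    return labels, manifest


def run_enrich(cfg: RunConfig, matrix: ScoreMatrix | None = None) -> dict:
    """Per-ligand retrospective metrics against the actives table."""
    if not cfg.actives:
        raise ValueError("enrich needs --actives")
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        if not cfg.scores:
            raise ValueError("enrich needs --scores (aggregated matrix CSV)")
        matrix = ScoreMatrix.from_csv(cfg.scores)
    actives = read_actives(cfg.actives, pchembl_min=cfg.pchembl_min)
    rows = []
    skipped: list[str] = []
    for ligand in matrix.ligands:
        try:
            rep = evaluate_ligand(matrix, ligand, actives, alpha=cfg.alpha,
                                  fractions=cfg.ef_fractions, bins=cfg.tg_bins)
        except EnrichError as exc:
            log.warning("skipping %s: %s", ligand, exc)
            skipped.append(ligand)
            continue
        (out / f"enrichment_{ligand}.json").write_text(
            json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n")
        rep.roc_to_csv(out / f"roc_{ligand}.csv")
        row = {"ligand_id": ligand, "auc": rep.auc}
        row.update({f"ef_{k}": v for k, v in rep.ef.items()})
        row.update({"rie": rep.rie, "bedroc": rep.bedroc, "tg": rep.tg,
                    "n_actives": rep.n_actives})
        rows.append(row)
    if not rows:
        raise EnrichError("no ligand had usable actives")
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "enrichment_summary.csv", index=False)
    manifest = {
        "stage": "enrich",
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {"actives": cfg.actives},
        "parameters": {"alpha": cfg.alpha, "ef_fractions": list(cfg.ef_fractions),
                       "tg_bins": cfg.tg_bins, "pchembl_min": cfg.pchembl_min},
        "counts": {"ligands_evaluated": len(rows),
                   "ligands_skipped": len(skipped),
                   "active_pairs": len(actives)},
        "outputs": {"summary": str(out / "enrichment_summary.csv")},
    }
    _write_manifest(out, manifest)
    return manifest


def run_all(cfg: RunConfig,
            target_classes: dict[str, str] | None = None) -> dict:
    """Aggregate -> fingerprint -> cluster -> enrich (enrich if actives given)."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    matrix, m_agg = run_aggregate(cfg)
    fps, m_fp = run_fingerprint(cfg, matrix=matrix, target_classes=target_classes)
    _, m_cl = run_cluster(cfg, fps=fps)
    stages = {"aggregate": m_agg, "fingerprint": m_fp, "cluster": m_cl}
    if cfg.actives:
        stages["enrich"] = run_enrich(cfg, matrix=matrix)
    manifest = {
        "stage": "all",
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {"scores": cfg.scores, "chain_map": cfg.chain_map,
                   "actives": cfg.actives},
        "parameters": {
            "top_k": cfg.top_k, "z_cut": cfg.z_cut,
            "min_ligands": cfg.min_ligands, "alpha": cfg.alpha,
            "ef_fractions": list(cfg.ef_fractions), "tg_bins": cfg.tg_bins,
            "pchembl_min": cfg.pchembl_min, "cut_k": cfg.cut_k,
            "cut_height": cfg.cut_height,
            "exclude": list(cfg.exclude), "include": list(cfg.include)},
        "stages": stages,
    }
    _write_manifest(out, manifest)
    return manifest
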