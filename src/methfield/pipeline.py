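"""End-to-end orchestration: simulate/load -> segment -> quantify -> test -> enrich.

Every output TSV/BED carries a leading ``# config_hash=...`` comment so a
bundle can be traced to the exact configuration that produced it; an
identical config (seed included) reproduces every output byte for byte.
A run manifest (``run.json``) lists the config, its hash and the files
written.  A standard PCA of the corrected block matrix (per-block mean
imputation, centered SVD) is included as a report convenience.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import differential, enrichment, io, quantify, segmentation
from .simulate import SimulationConfig, simulate_dataset, synthetic_gene_model

log = logging.getLogger("methfield")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """One run of the pipeline.

    With ``simulate=True`` the input bundle is drawn from *simulation*
    (plus a synthetic gene model for the annotation/enrichment stages);
    otherwise *manifest_path*, *panel_path* and optionally
    *gene_model_path* / *tf_list_path* point at real inputs.
    """

    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    block_params: segmentation.BlockParams = field(default_factory=segmentation.BlockParams)
    thresholds: differential.Thresholds = field(default_factory=differential.Thresholds)
    manifest_path: str = ""
    panel_path: str = ""
    gene_model_path: str = ""
    tf_list_path: str = ""
    min_depth: int = 5
    min_chh_reads: int = 20
    error_mode: str = "block"
    min_tumor_fraction: float = 0.10
    use_true_blocks: bool = False  # simulate mode: skip re-segmentation
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pca_coordinates(matrix: quantify.BlockMatrix, n_components: int = 5) -> pd.DataFrame:
    """Sample coordinates of a centered-SVD PCA of the block matrix.

    Missing entries are imputed with the block mean; all-missing blocks are
    dropped.
    """
    from sklearn.decomposition import PCA

    X = matrix.values.to_numpy(dtype=float).T  # samples x blocks
    keep = ~np.all(np.isnan(X), axis=0)
    X = X[:, keep]
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    tissue = {s.sample_id: s.tissue for s in matrix.manifest}
    out = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    out.insert(0, "sample_id", matrix.sample_ids)
    out.insert(1, "tissue", [tissue[s] for s in matrix.sample_ids])
    for i in range(k):
        out[f"PC{i + 1}_varfrac"] = pca.explained_variance_ratio_[i]
    return out


def _load_real_inputs(cfg: PipelineConfig):
    manifest = io.apply_inclusion_rules(
        io.read_manifest(cfg.manifest_path), cfg.min_tumor_fraction
    )
    panel = io.read_panel_bed(cfg.panel_path) if cfg.panel_path else None
    per_sample = {}
    for s in manifest:
        df = io.read_cytosine_report(s.path, min_depth=cfg.min_depth)
        per_sample[s.sample_id] = io.collapse_cpg_strands(df)
    records = io.stack_records(per_sample)
    transcripts = (
        segmentation.read_gene_model_bed12(cfg.gene_model_path)
        if cfg.gene_model_path
        else None
    )
    tf_genes = (
        enrichment.read_gene_list(cfg.tf_list_path) if cfg.tf_list_path else None
    )
    return records, manifest, panel, transcripts, tf_genes, None


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages and write the output bundle into *outdir*.

    Returns a dict of in-memory results (records, blocks, matrix, DMR
    tables, summary, paths).  Any stage failure raises :class:`StageError`
    and removes files written by the failed run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    chash = cfg.config_hash()
    stamp = f"config_hash={chash}"
    written: list[Path] = []

    def _write_table(df, name):
        path = outdir / name
        io.write_table(df, path, header=stamp)
        written.append(path)
        return path

    result: dict = {"config_hash": chash}
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "simulate" if cfg.simulate else "load"
        truth = None
        if cfg.simulate:
            sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
            ds = simulate_dataset(sim)
            records, manifest, panel = ds.records, ds.manifest, ds.panel
            truth = ds.truth
            transcripts, tf_genes = synthetic_gene_model(ds.blocks, seed=cfg.seed)
            depth = records["meth_count"] + records["unmeth_count"]
            records = records[depth >= cfg.min_depth].reset_index(drop=True)
            _write_table(truth, "truth.tsv")
        else:
            records, manifest, panel, transcripts, tf_genes, truth = _load_real_inputs(cfg)
        io.write_manifest(manifest, outdir / "samples.tsv")
        written.append(outdir / "samples.tsv")
        if panel is not None:
            io.write_panel_bed(panel, outdir / "panel.bed")
            written.append(outdir / "panel.bed")
        result.update(records=records, manifest=manifest, truth=truth)

        # ---- segmentation -------------------------------------------------
        stage = "segment"
        if cfg.simulate and cfg.use_true_blocks:
            blocks = ds.blocks
        else:
            blocks = segmentation.build_blocks(
                records, cfg.block_params, panel, min_depth=cfg.min_depth
            )
        if transcripts is not None:
            blocks = segmentation.annotate_blocks(blocks, transcripts)
        io.write_blocks_bed(blocks, outdir / "blocks.bed", header=stamp)
        written.append(outdir / "blocks.bed")
        _write_table(segmentation.blocks_to_frame(blocks), "blocks.tsv")
        result["blocks"] = blocks
        log.info("segmented %d blocks", len(blocks))

        # ---- quantification -----------------------------------------------
        stage = "quantify"
        matrix = quantify.build_block_matrix(
            records, blocks, manifest,
            min_chh_reads=cfg.min_chh_reads, error_mode=cfg.error_mode,
        )
        vals = matrix.values.reset_index()
        _write_table(vals, "block_matrix.tsv")
        _write_table(
            matrix.sample_error.rename_axis("sample_id").reset_index(), "sample_error.tsv"
        )
        result["matrix"] = matrix

        # ---- differential -------------------------------------------------
        stage = "dmr"
        gene_map = {b.block_id: b.genes for b in blocks}
        tumor = differential.call_tumor_dmrs(matrix, cfg.thresholds, gene_map)
        _write_table(tumor, "tumor_dmrs.tsv")
        result["tumor_dmrs"] = tumor

        stage = "fc"
        fc = differential.call_fc_dmrs(matrix, cfg.thresholds, gene_map)
        _write_table(fc, "fc_patterns.tsv")
        n_overlap, pct = differential.overlap_sets(fc["block_id"], tumor["block_id"])
        overlap = pd.DataFrame(
            {
                "n_fc": [len(fc)],
                "n_tumor": [len(tumor)],
                "n_overlap": [n_overlap],
                "pct_fc_overlapping": [pct],
            }
        )
        _write_table(overlap, "overlap_summary.tsv")
        result.update(fc_patterns=fc, overlap=overlap)

        # ---- enrichment ---------------------------------------------------
        stage = "enrich"
        if transcripts is not None and tf_genes:
            universe = enrichment.map_dmrs_to_genes(
                [b.block_id for b in blocks], gene_map
            )
            query = enrichment.map_dmrs_to_genes(fc["block_id"], gene_map)
            if query:
                res = enrichment.test_enrichment(query, universe, tf_genes)
                enr = pd.DataFrame([dataclasses.asdict(res)])
            else:
                enr = pd.DataFrame(
                    columns=["universe_size", "set_size_in_universe", "query_size",
                             "overlap", "p_hypergeom", "fold_enrichment"]
                )
            _write_table(enr, "enrichment.tsv")
            result["enrichment"] = enr

        # ---- PCA report ---------------------------------------------------
        stage = "pca"
        pca = _pca_coordinates(matrix)
        _write_table(pca, "pca.tsv")
        result["pca"] = pca

        # ---- run manifest -------------------------------------------------
        stage = "manifest"
        run_info = {
            "config": dataclasses.asdict(cfg),
            "config_hash": chash,
            "outputs": sorted(p.name for p in written),
        }
        (outdir / "run.json").write_text(json.dumps(run_info, indent=2, default=str) + "\n")
        result["outdir"] = outdir
        return result
    except Exception as exc:  # partial outputs are removed
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc


def summarize_run(outdir) -> pd.DataFrame:
    """Recount the bundle's TSVs into a one-row summary table."""
    outdir = Path(outdir)
    need = ["blocks.tsv", "tumor_dmrs.tsv", "fc_patterns.tsv", "overlap_summary.tsv"]
    for name in need:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing pipeline output {name} in {outdir}")
    blocks = io.read_table(outdir / "blocks.tsv")
    tumor = io.read_table(outdir / "tumor_dmrs.tsv")
    fc = io.read_table(outdir / "fc_patterns.tsv")
    overlap = io.read_table(outdir / "overlap_summary.tsv")
    n_overlap, pct = differential.overlap_sets(
        fc["block_id"] if len(fc) else [], tumor["block_id"] if len(tumor) else []
    )
    row = {
        "n_blocks": len(blocks),
        "n_tumor_dmrs": len(tumor),
        "n_tumor_hyper": int((tumor["direction"] == "hyper").sum()) if len(tumor) else 0,
        "n_tumor_hypo": int((tumor["direction"] == "hypo").sum()) if len(tumor) else 0,
        "n_fc": len(fc),
        "n_fc_up": int((fc["category"] == "up").sum()) if len(fc) else 0,
        "n_fc_down": int((fc["category"] == "down").sum()) if len(fc) else 0,
        "n_overlap": n_overlap,
        "pct_fc_overlapping": pct,
    }
    stored = overlap.iloc[0]
    if int(stored["n_overlap"]) != n_overlap:
        raise ValueError("stored overlap summary disagrees with recount")
    return pd.DataFrame([row])
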