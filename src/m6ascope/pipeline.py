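"""End-to-end orchestration: images -> linked single cells -> m6A levels.

Stage order follows the experiment: nanowell scan analysis (cell
detection, phenotyping, occupancy matrix), flow-cell spot detection
(polyA and m6A channels, colocalization), RNA density matrix, matrix
registration, singlet linking, m6A level computation, then optional
seqFISH decoding / normalization / embedding when hybridization rounds
are present.  Each stage failure aborts with the stage name; partial
results computed so far are retained on the result object.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colocalize import align_rounds, match_spots, shift_spots
from .config import PipelineConfig
from .quantify import (ExpressionMatrix, NormalizedMatrix, cell_m6a_level,
                       decode_seqfish, embed_cells, normalize_expression,
                       qc_cells)
from .registration import (DensityMatrix, OccupancyMatrix, build_com,
                           build_rdm, classify_phenotype, detect_cells,
                           link_single_cells, register_rdm_to_com)
from .simulate import (BEAD_CHANNEL, M6A_CHANNEL, POLYA_CHANNEL,
                       READOUT_CHANNEL, SimulatedExperiment)
from .spots import Image, SpotSet, detect_spots

__all__ = ["PipelineResult", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, in memory."""

    config: PipelineConfig
    cells: pd.DataFrame | None = None
    com: OccupancyMatrix | None = None
    fov_spots: dict = field(default_factory=dict)   # (r, c) -> {channel: SpotSet}
    rdm: DensityMatrix | None = None
    registration: "object | None" = None
    linked: pd.DataFrame | None = None
    expression: ExpressionMatrix | None = None
    normalized: NormalizedMatrix | None = None
    qc_pass: pd.Series | None = None
    embedding: np.ndarray | None = None
    manifest: dict = field(default_factory=dict)

    def save(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.cells is not None:
            self.cells.to_csv(out / "cells.csv", index=False)
        if self.com is not None:
            pd.DataFrame(self.com.counts).to_csv(out / "com.csv", index=False,
                                                 header=False)
        if self.rdm is not None:
            pd.DataFrame(self.rdm.total).to_csv(out / "rdm_total.csv",
                                                index=False, header=False)
            pd.DataFrame(self.rdm.modified).to_csv(out / "rdm_m6a.csv",
                                                   index=False, header=False)
        if self.registration is not None:
            (out / "registration.json").write_text(json.dumps({
                "offset": list(self.registration.offset),
                "correlation": self.registration.correlation,
                "z_score": self.registration.z_score,
                "valid": self.registration.valid,
            }, indent=2))
        if self.linked is not None:
            self.linked.to_csv(out / "linked_cells.csv", index=False)
        if self.expression is not None:
            self.expression.counts.to_csv(out / "expression.csv")
            self.expression.cell_annotations.to_csv(out / "cell_annotations.csv")
            if self.expression.gene_modified is not None:
                self.expression.gene_modified.to_csv(out / "expression_m6a.csv")
        if self.normalized is not None:
            self.normalized.values.to_csv(out / "expression_normalized.csv")
        if self.embedding is not None:
            pd.DataFrame(self.embedding, columns=["tsne1", "tsne2"]).to_csv(
                out / "embedding.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2,
                                                      default=str))
        return out


def _config_hash(cfg: PipelineConfig) -> str:
    from dataclasses import asdict
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _detect_channel(img: np.ndarray, channel: str, rnd: int,
                    cfg: PipelineConfig) -> SpotSet:
    return detect_spots(
        Image(img, channel=channel, round=rnd),
        threshold=cfg.detection_threshold,
        background_radius=cfg.background_radius,
        smooth_sigma=cfg.smooth_sigma,
        fit_window=cfg.fit_window,
        merge_radius=cfg.merge_radius,
        threshold_k=cfg.threshold_k,
    )


def run_pipeline(exp: SimulatedExperiment, cfg: PipelineConfig,
                 outdir=None) -> PipelineResult:
    """Run the full analysis on a (simulated or loaded) experiment bundle.

    ``exp`` provides the nanowell scan, per-FOV image stacks and scan
    geometry; ground truth, if present, is never consulted.  Results are
    returned in memory and, when ``outdir`` is given, written as CSV/JSON
    with a run manifest.
    """
    cfg.validate()
    res = PipelineResult(config=cfg)
    res.manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                    "version": __version__, "stages": []}

    def stage(name):
        res.manifest["stages"].append(name)

    # --- nanowell scan ---
    try:
        stage("detect_cells")
        cells = detect_cells(exp.nanowell_scan, exp.scan_origin,
                             exp.well_pitch_px, cfg.com_shape)
        if cfg.phenotype_gates:
            cells = classify_phenotype(cells, cfg.phenotype_gates)
        res.cells = cells
        stage("build_com")
        res.com = build_com(cells, cfg.com_shape)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("nanowell_scan", str(e)) from e

    # --- flow-cell spot detection and RDM ---
    try:
        stage("detect_spots")
        fov_counts: dict[tuple[int, int], tuple[int, int]] = {}
        for pos, rounds in exp.fovs.items():
            imgs = rounds.get(0, {})
            if POLYA_CHANNEL not in imgs:
                continue
            total_ss = _detect_channel(imgs[POLYA_CHANNEL], POLYA_CHANNEL, 0, cfg)
            chans = {POLYA_CHANNEL: total_ss}
            n_mod = 0
            if M6A_CHANNEL in imgs:
                m6a_ss = _detect_channel(imgs[M6A_CHANNEL], M6A_CHANNEL, 0, cfg)
                chans[M6A_CHANNEL] = m6a_ss
                m = match_spots(total_ss.ok_spots(), m6a_ss.ok_spots(),
                                max_dist=cfg.match_radius_px)
                n_mod = m.n_matched
            res.fov_spots[pos] = chans
            fov_counts[pos] = (len(total_ss.ok_spots()), n_mod)
        stage("build_rdm")
        res.rdm = build_rdm(fov_counts, cfg.rdm_shape)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("flow_cell_detection", str(e)) from e

    # --- registration and linking ---
    try:
        stage("register")
        res.registration = register_rdm_to_com(
            res.rdm, res.com, z_threshold=cfg.registration_z_threshold)
        stage("link_single_cells")
        res.linked = link_single_cells(res.registration, res.com, res.cells,
                                       res.rdm)
        if len(res.linked):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res.linked["m6a_level"] = [
                    cell_m6a_level(t, m) for t, m in
                    zip(res.linked.total_count, res.linked.m6a_count)]
    except Exception as e:  # noqa: BLE001
        raise PipelineError("registration", str(e)) from e

    # --- seqFISH decoding (optional) ---
    if cfg.round_gene_map:
        try:
            stage("decode_seqfish")
            res.expression = _decode_stage(exp, cfg, res)
            stage("normalize")
            res.normalized = normalize_expression(res.expression)
            if cfg.min_housekeeping_detect > 0:
                res.qc_pass = qc_cells(res.expression,
                                       list(cfg.housekeeping_genes),
                                       cfg.min_housekeeping_detect)
            n_cells = len(res.expression.cells)
            if n_cells >= 3 * cfg.perplexity:
                stage("embed")
                res.embedding = embed_cells(res.normalized,
                                            perplexity=cfg.perplexity,
                                            seed=cfg.seed)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("seqfish", str(e)) from e

    if outdir is not None:
        res.save(outdir)
    return res


def _decode_stage(exp: SimulatedExperiment, cfg: PipelineConfig,
                  res: PipelineResult) -> ExpressionMatrix:
    """Detect, align and decode the hybridization rounds for linked singlets."""
    linked = res.linked if res.linked is not None else pd.DataFrame()
    singlet_fovs = {(int(r.fov_row), int(r.fov_col)): f"{int(r.well_row)}_{int(r.well_col)}"
                    for r in linked.itertuples()} if len(linked) else {}
    per_cell: dict[str, dict[int, SpotSet]] = {}
    m6a_maps: dict[str, SpotSet] = {}
    annos: dict[str, dict] = {}
    for pos, cell_id in singlet_fovs.items():
        rounds = exp.fovs.get(pos, {})
        ref_beads = rounds.get(0, {}).get(BEAD_CHANNEL)
        chans0 = res.fov_spots.get(pos, {})
        if M6A_CHANNEL in chans0:
            m6a_maps[cell_id] = chans0[M6A_CHANNEL].ok_spots()
        per_round: dict[int, SpotSet] = {}
        for rnd in sorted(cfg.round_gene_map):
            imgs = rounds.get(rnd)
            if imgs is None or READOUT_CHANNEL not in imgs:
                continue
            ss = _detect_channel(imgs[READOUT_CHANNEL], READOUT_CHANNEL, rnd, cfg)
            if ref_beads is not None and BEAD_CHANNEL in imgs:
                off = align_rounds(Image(imgs[BEAD_CHANNEL], round=rnd),
                                   Image(ref_beads, round=0))
                ss = shift_spots(ss, off)
            per_round[rnd] = ss.ok_spots()
        per_cell[cell_id] = per_round
        row = linked[(linked.fov_row == pos[0]) & (linked.fov_col == pos[1])].iloc[0]
        annos[cell_id] = {"phenotype": row.phenotype,
                          "well_row": int(row.well_row),
                          "well_col": int(row.well_col),
                          "total_polya": int(row.total_count),
                          "m6a_count": int(row.m6a_count)}
    anno_df = pd.DataFrame.from_dict(annos, orient="index")
    anno_df.index.name = "cell"
    em = decode_seqfish(per_cell, cfg.round_gene_map,
                        m6a_spots=m6a_maps or None,
                        cell_annotations=anno_df if len(anno_df) else None,
                        match_radius=cfg.match_radius_px)
    return em
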