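"""Disk formats: TIFF image stacks, CSV tables, FASTA sequences.

A simulated experiment serializes to a directory:

    scan.tif            nanowell scan, one page per channel
    fov_r{row}_c{col}.tif   one page per (round, channel), metadata in the
                            ImageDescription tag
    wells.csv, molecules.csv, spots.csv, beads.csv   ground truth
    truth.json          offsets, planted fractions, seed
    config.yaml         simulation geometry

Probes and transcripts are written as FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probes import PrimaryProbe, gc_percent
from .transcripts import SimulatedTranscript

__all__ = [
    "save_experiment",
    "load_experiment_images",
    "write_probe_fasta",
    "write_transcript_fasta",
    "write_matrix_csv",
]


def save_experiment(exp, outdir) -> Path:
    """Write a SimulatedExperiment to ``outdir`` (created if needed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    channels = sorted(exp.nanowell_scan)
    tifffile.imwrite(
        out / "scan.tif",
        np.stack([exp.nanowell_scan[c].astype(np.float32) for c in channels]),
        photometric="minisblack",
        description=json.dumps({"channels": channels,
                                "origin": list(exp.scan_origin),
                                "well_pitch_px": exp.well_pitch_px}),
    )
    for (fr, fc), rounds in exp.fovs.items():
        pages, meta = [], []
        for rnd in sorted(rounds):
            for ch in sorted(rounds[rnd]):
                pages.append(rounds[rnd][ch].astype(np.float32))
                meta.append({"round": rnd, "channel": ch})
        tifffile.imwrite(out / f"fov_r{fr:03d}_c{fc:03d}.tif",
                         np.stack(pages), photometric="minisblack",
                         description=json.dumps({"pages": meta}))
    t = exp.truth
    t.wells.to_csv(out / "wells.csv", index=False)
    t.well_molecules.to_csv(out / "molecules.csv", index=False)
    t.spot_truth.to_csv(out / "spots.csv", index=False)
    t.beads.to_csv(out / "beads.csv", index=False)
    (out / "truth.json").write_text(json.dumps({
        "rdm_offset": list(t.rdm_offset),
        "round_offsets": {str(k): list(v) for k, v in t.round_offsets.items()},
        "m6a_fractions": t.m6a_fractions,
        "seed": t.seed,
    }, indent=2))
    return out


def load_experiment_images(indir):
    """Read back the image part of a saved experiment.

    Returns (scan dict, scan metadata dict, fovs nested dict keyed like
    ``SimulatedExperiment.fovs``).
    """
    indir = Path(indir)
    with tifffile.TiffFile(indir / "scan.tif") as tf:
        meta = json.loads(tf.pages[0].description)
        stack = tf.asarray()
    scan = {c: stack[i].astype(float) for i, c in enumerate(meta["channels"])}
    fovs: dict[tuple[int, int], dict[int, dict[str, np.ndarray]]] = {}
    for path in sorted(indir.glob("fov_r*_c*.tif")):
        name = path.stem  # fov_rRRR_cCCC
        fr = int(name.split("_")[1][1:])
        fc = int(name.split("_")[2][1:])
        with tifffile.TiffFile(path) as tf:
            pm = json.loads(tf.pages[0].description)["pages"]
            stack = tf.asarray()
        if stack.ndim == 2:
            stack = stack[None]
        d: dict[int, dict[str, np.ndarray]] = {}
        for page, info in zip(stack, pm):
            d.setdefault(int(info["round"]), {})[info["channel"]] = page.astype(float)
        fovs[(fr, fc)] = d
    return scan, meta, fovs


def write_probe_fasta(oligos: dict[str, list[PrimaryProbe]], path,
                      readout_ids: dict[str, str] | None = None) -> None:
    """Write assembled primary probes, header ``gene|start|end|gc|readout_id``."""
    records = []
    for gene, probes in oligos.items():
        rid = (readout_ids or {}).get(gene, "readout")
        for p in probes:
            gc = gc_percent(p.target)
            header = f"{gene}|{p.start}|{p.end}|{gc:.1f}|{rid}"
            records.append(SeqRecord(Seq(p.full_sequence), id=header,
                                     description=""))
    SeqIO.write(records, str(path), "fasta")


def write_transcript_fasta(transcripts: list[SimulatedTranscript], path) -> None:
    records = []
    for i, t in enumerate(transcripts):
        mods = ",".join(map(str, t.modified_positions)) or "-"
        records.append(SeqRecord(Seq(t.sequence), id=f"ivt_{i}",
                                 description=f"m6a_positions={mods}"))
    SeqIO.write(records, str(path), "fasta")


def write_matrix_csv(matrix: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(path, index=False, header=False)
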