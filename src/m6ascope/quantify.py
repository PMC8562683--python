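"""m6A level calculation, seqFISH decoding, normalization, embedding, QC.

m6A levels are binomial fractions of modified molecules:

* single-cell level = (m6A+ molecule count) / (total polyA+ count) in the
  cell's nanowell;
* per-gene level = (modified gene-specific transcripts) / (total
  gene-specific transcripts), reported only when the total count is >= 10
  or the log-mean expression is >= 0.02 (otherwise "not applicable").

seqFISH rounds are decoded one gene per round: the per-well count for a
gene is the spot count of its round within the well's FOV, and coupling
against the pre-seqFISH m6A spot map (1-px colocalization) yields
per-(gene, cell) modified counts.

Expression is normalized per cell by total captured molecules, log2
transformed, and gene-centred; cells embed with t-SNE at perplexity 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .colocalize import match_spots
from .spots import SpotSet

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "cell_m6a_level",
    "gene_m6a_level",
    "decode_seqfish",
    "normalize_expression",
    "embed_cells",
    "qc_cells",
]

#: Default reliability filters for per-gene m6A levels.
MIN_GENE_TOTAL = 10
LOG_EXPR_THRESHOLD = 0.02


@dataclass
class ExpressionMatrix:
    """Gene x cell counts with per-cell totals and modification counts.

    ``counts``: genes as rows, cells as columns (integer molecule counts
    from seqFISH decoding).  ``cell_annotations``: one row per cell (index
    aligned with columns) with at least ``total_polya`` and ``m6a_count``;
    phenotype / well columns optional.  ``gene_modified``: same shape as
    ``counts``, per-(gene, cell) modified molecule counts when modification
    imaging and seqFISH are coupled.
    """

    counts: pd.DataFrame
    cell_annotations: pd.DataFrame
    gene_modified: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.cell_annotations.index):
            raise ValueError("cell annotations must be indexed by cell id")
        if self.gene_modified is not None:
            if (not self.gene_modified.index.equals(self.counts.index)
                    or not self.gene_modified.columns.equals(self.counts.columns)):
                raise ValueError("gene_modified must align with counts")
            if (self.gene_modified.to_numpy() > self.counts.to_numpy()).any():
                raise ValueError("modified counts exceed totals for some (gene, cell)")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cells(self) -> list:
        return list(self.counts.columns)


@dataclass
class NormalizedMatrix:
    """Gene x cell values after per-cell normalization, log2, gene centring."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        centred = self.values.sub(self.values.mean(axis=1), axis=0)
        if not np.allclose(centred.to_numpy(), self.values.to_numpy(), atol=1e-9):
            raise ValueError("gene rows must be mean-centred")


def cell_m6a_level(total: float, modified: float) -> float:
    """Single-cell m6A level: modified / total molecule counts.

    Returns NaN (with a warning) when the total is zero; raises if
    ``modified`` exceeds ``total`` since that indicates an upstream bug.
    """
    if total < 0 or modified < 0:
        raise ValueError("counts must be non-negative")
    if modified > total:
        raise ValueError(f"modified count {modified} exceeds total {total}")
    if total == 0:
        warnings.warn("zero total count: m6A level undefined")
        return float("nan")
    return modified / total


def gene_m6a_level(gene_total: float, gene_modified: float,
                   log_mean_expr: float | None = None,
                   *,
                   min_total: int = MIN_GENE_TOTAL,
                   log_expr_threshold: float = LOG_EXPR_THRESHOLD) -> float:
    """Per-gene m6A level with reliability filters.

    Returns modified/total when ``gene_total >= min_total`` or
    ``log_mean_expr >= log_expr_threshold``; otherwise NaN ("not
    applicable").  The default threshold is +0.02; pass
    ``log_expr_threshold=-0.02`` for the laxer variant.
    """
    if gene_modified > gene_total:
        raise ValueError(f"modified count {gene_modified} exceeds total {gene_total}")
    expr_ok = log_mean_expr is not None and log_mean_expr >= log_expr_threshold
    if gene_total >= min_total or expr_ok:
        if gene_total == 0:
            return float("nan")
        return gene_modified / gene_total
    return float("nan")


def decode_seqfish(
    round_spotsets: dict[int, SpotSet] | dict[tuple, dict[int, SpotSet]],
    round_gene_map: dict[int, str],
    *,
    m6a_spots: "SpotSet | dict | None" = None,
    cell_annotations: pd.DataFrame | None = None,
    match_radius: float = 1.0,
) -> ExpressionMatrix:
    """Decode one-gene-per-round seqFISH spot sets into an expression matrix.

    Parameters
    ----------
    round_spotsets
        Either ``{round: SpotSet}`` for a single cell/FOV, or
        ``{cell_id: {round: SpotSet}}`` for many cells.  Spot sets must
        already be expressed in the reference (round-0) coordinate frame.
    round_gene_map
        Round index -> gene name; every provided round must be mapped.
    m6a_spots
        The pre-seqFISH modification spot map (one SpotSet, or
        ``{cell_id: SpotSet}``); when given, per-(gene, cell) modified
        counts are obtained by 1-px colocalization of each round's spots
        against it.
    cell_annotations
        Optional per-cell metadata (phenotype, well, total_polya,
        m6a_count); defaults to totals derived from the decoded counts.
    """
    # normalize to {cell_id: {round: SpotSet}}
    first_val = next(iter(round_spotsets.values()), None)
    if first_val is None:
        per_cell: dict = {}
    elif isinstance(first_val, SpotSet):
        per_cell = {0: round_spotsets}  # single unnamed cell
    else:
        per_cell = round_spotsets  # type: ignore[assignment]
    for cid, rounds in per_cell.items():
        for rnd in rounds:
            if rnd not in round_gene_map:
                raise ValueError(f"round {rnd} (cell {cid!r}) has no gene mapping")
    genes = [round_gene_map[r] for r in sorted(round_gene_map)]
    cells = list(per_cell)
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(cells, name="cell"))
    modified = pd.DataFrame(0, index=counts.index, columns=counts.columns)
    m6a_per_cell: dict = {}
    if isinstance(m6a_spots, SpotSet):
        m6a_per_cell = {cid: m6a_spots for cid in cells}
    elif isinstance(m6a_spots, dict):
        m6a_per_cell = m6a_spots
    for cid, rounds in per_cell.items():
        for rnd, ss in rounds.items():
            gene = round_gene_map[rnd]
            ok = ss.ok_spots()
            counts.loc[gene, cid] += len(ok)
            ref = m6a_per_cell.get(cid)
            if ref is not None and len(ok) and len(ref.ok_spots()):
                m = match_spots(ok, ref.ok_spots(), max_dist=match_radius)
                modified.loc[gene, cid] += m.n_matched
    if cell_annotations is None:
        cell_annotations = pd.DataFrame(
            {"total_polya": counts.sum(axis=0),
             "m6a_count": modified.sum(axis=0)})
        cell_annotations.index = counts.columns
    gene_modified = modified if m6a_per_cell else None
    return ExpressionMatrix(counts=counts, cell_annotations=cell_annotations,
                            gene_modified=gene_modified)


def normalize_expression(matrix: ExpressionMatrix,
                         pseudocount: float | None = None) -> NormalizedMatrix:
    """Per-cell normalization, log2, and gene mean-centring.

    value(g, c) = log2(count(g, c) / total(c) + pseudocount) minus the
    gene's mean across cells.  ``total(c)`` is the cell's total captured
    molecule count (``total_polya`` annotation when present, else the
    column sum).  The pseudocount defaults to 1/total per cell so a zero
    count behaves like a fractional single molecule; cells with zero total
    are excluded with a warning.
    """
    counts = matrix.counts.astype(float)
    if "total_polya" in matrix.cell_annotations.columns:
        totals = matrix.cell_annotations["total_polya"].astype(float)
    else:
        totals = counts.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"excluding {(~keep).sum()} cells with zero total count")
    counts = counts.loc[:, keep[keep].index]
    totals = totals[keep]
    frac = counts.div(totals, axis=1)
    pc = (1.0 / totals) if pseudocount is None else pseudocount
    logv = np.log2(frac.add(pc, axis=1) if pseudocount is None else frac + pc)
    centred = logv.sub(logv.mean(axis=1), axis=0)
    return NormalizedMatrix(values=centred)


def embed_cells(norm: NormalizedMatrix, perplexity: float = 10.0,
                seed: int = 0) -> np.ndarray:
    """t-SNE embedding of cells (columns) into 2D, deterministic per seed."""
    X = norm.values.to_numpy().T  # cells x genes
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity}; "
            "lower the perplexity (need >= 3 x perplexity cells)"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
              init="pca")
    return ts.fit_transform(X)


def qc_cells(matrix: ExpressionMatrix,
             housekeeping: list[str] = ("GAPDH", "ENO1", "EEF2"),
             min_detect: int = 1) -> pd.Series:
    """Housekeeping-gene quality control.

    A cell passes when at least ``min_detect`` of the housekeeping genes
    have nonzero counts.  All housekeeping genes must be in the panel.
    """
    missing = [g for g in housekeeping if g not in matrix.counts.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from panel: {missing}")
    detected = (matrix.counts.loc[list(housekeeping)] > 0).sum(axis=0)
    return detected >= min_detect
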