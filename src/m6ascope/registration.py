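"""Nanowell scan <-> flow-cell registration.

The low-magnification nanowell scan yields a cell occupancy matrix
(COM, default 121 x 381): cells are found on the nuclear-stain channel,
phenotyped on the dye channels, and counted per well.  The high-
magnification flow-cell scan yields an RNA density matrix (RDM, default
31 x 51): per-FOV molecule counts in the polyA and modification channels.
Because the flow-cell coverslip is detached from the nanowell array, the
RDM's position within the COM is unknown; it is recovered by computing the
Pearson correlation between the RDM and every contiguous same-shape COM
subset and declaring the maximum an outlier of the correlation-map
distribution (z-score threshold, default 5).  Registered wells holding
exactly one cell are then linked to their molecular readouts; empty wells
and doublets are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

__all__ = [
    "OccupancyMatrix",
    "DensityMatrix",
    "RegistrationResult",
    "RegistrationError",
    "detect_cells",
    "classify_phenotype",
    "build_com",
    "build_rdm",
    "register_rdm_to_com",
    "link_single_cells",
]


class RegistrationError(RuntimeError):
    """Raised when the RDM cannot be placed in the COM reliably."""


@dataclass
class OccupancyMatrix:
    """Per-well cell counts, plus how many detections fell outside the grid."""

    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("occupancy counts must be a 2D non-negative grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class DensityMatrix:
    """Per-FOV molecule counts: total polyA+ and modified, plus a missing mask."""

    total: np.ndarray
    modified: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=float)
        self.modified = np.asarray(self.modified, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.total.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.total.shape != self.modified.shape:
            raise ValueError("total and modified grids must share a shape")
        valid = ~self.missing
        if np.any(self.modified[valid] > self.total[valid]):
            raise ValueError("modified count exceeds total count in some FOV")

    @property
    def shape(self) -> tuple[int, int]:
        return self.total.shape


@dataclass
class RegistrationResult:
    """Best RDM placement in the COM with its correlation map and outlier score."""

    offset: tuple[int, int]
    correlation: float
    correlation_map: np.ndarray
    z_score: float
    z_threshold: float = 5.0

    @property
    def valid(self) -> bool:
        return bool(np.isfinite(self.z_score) and self.z_score >= self.z_threshold)


def detect_cells(
    scan: dict[str, np.ndarray],
    origin: tuple[float, float],
    well_pitch: float,
    grid: tuple[int, int],
    *,
    nuclear_channel: str = "nuclear",
    smooth_sigma: float = 1.0,
    threshold: float | None = None,
    threshold_k: float = 8.0,
    min_distance: int = 2,
    sample_radius: float = 2.0,
) -> pd.DataFrame:
    """Find cells on the nanowell scan and measure per-channel intensities.

    Local maxima on the (smoothed) nuclear-stain channel above a threshold
    mark cell positions; each channel's intensity is the mean over a disk of
    ``sample_radius`` pixels around the maximum.  Cells are assigned to the
    nearest well of the grid defined by ``origin`` (pixel centre of well
    (0, 0)) and ``well_pitch``.

    Returns a DataFrame with columns row, col (scan px), well_row, well_col,
    in_grid, and one intensity column per non-nuclear channel.
    """
    if nuclear_channel not in scan:
        raise ValueError(f"nuclear channel {nuclear_channel!r} missing from scan")
    nuc = ndimage.gaussian_filter(np.asarray(scan[nuclear_channel], float),
                                  smooth_sigma, mode="nearest")
    if threshold is None:
        med = float(np.median(nuc))
        mad = float(np.median(np.abs(nuc - med))) * 1.4826
        threshold = med + threshold_k * max(mad, 1e-12)
    peaks = peak_local_max(nuc, min_distance=min_distance,
                           threshold_abs=threshold, exclude_border=False)
    rows = []
    rr, cc = np.mgrid[0:nuc.shape[0], 0:nuc.shape[1]]
    for pr, pc in peaks:
        disk = (rr - pr) ** 2 + (cc - pc) ** 2 <= sample_radius**2
        rec = {"row": float(pr), "col": float(pc)}
        for ch, img in scan.items():
            if ch == nuclear_channel:
                continue
            rec[ch] = float(np.asarray(img, float)[disk].mean())
        wr = int(round((pr - origin[0]) / well_pitch))
        wc = int(round((pc - origin[1]) / well_pitch))
        rec["well_row"], rec["well_col"] = wr, wc
        rec["in_grid"] = bool(0 <= wr < grid[0] and 0 <= wc < grid[1])
        rows.append(rec)
    chans = [c for c in scan if c != nuclear_channel]
    return pd.DataFrame(rows, columns=["row", "col", *chans,
                                       "well_row", "well_col", "in_grid"])


def _gates_overlap(g1: dict, g2: dict) -> bool:
    shared = set(g1) & set(g2)
    if not shared:
        return True  # unconstrained in each other's channels -> ambiguous
    for ch in shared:
        lo1, hi1 = g1[ch]
        lo2, hi2 = g2[ch]
        if hi1 < lo2 or hi2 < lo1:
            return False
    return True


def classify_phenotype(cells: pd.DataFrame,
                       gates: dict[str, dict[str, tuple[float, float]]]) -> pd.DataFrame:
    """Label cells by rectangular intensity gates.

    ``gates`` maps label -> {channel: (lo, hi)}; a cell gets the label of
    the unique gate containing it in every gated channel, else
    ``"unassigned"``.  Overlapping gates are a configuration error.
    """
    labels = list(gates)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if _gates_overlap(gates[a], gates[b]):
                raise ValueError(f"phenotype gates {a!r} and {b!r} overlap")
    out = cells.copy()

    def label_one(rec) -> str:
        for name, gate in gates.items():
            ok = True
            for ch, (lo, hi) in gate.items():
                v = rec[ch]
                if not (lo <= v <= hi):
                    ok = False
                    break
            if ok:
                return name
        return "unassigned"

    out["phenotype"] = [label_one(r) for _, r in cells.iterrows()]
    return out


def build_com(cells: pd.DataFrame, grid: tuple[int, int]) -> OccupancyMatrix:
    """Count assigned cells per well; out-of-grid cells are excluded with a tally."""
    counts = np.zeros(grid, dtype=int)
    if len(cells) == 0:
        return OccupancyMatrix(counts, 0)
    inside = cells["in_grid"] if "in_grid" in cells.columns else (
        (cells.well_row >= 0) & (cells.well_row < grid[0])
        & (cells.well_col >= 0) & (cells.well_col < grid[1])
    )
    kept = cells[inside.astype(bool)]
    n_excluded = int(len(cells) - len(kept))
    if n_excluded:
        warnings.warn(f"{n_excluded} cells outside the well grid were excluded")
    np.add.at(counts, (kept.well_row.to_numpy(int), kept.well_col.to_numpy(int)), 1)
    return OccupancyMatrix(counts, n_excluded)


def build_rdm(fov_counts: dict[tuple[int, int], tuple[int, int]],
              shape: tuple[int, int]) -> DensityMatrix:
    """Assemble the RNA density matrix from per-FOV (total, modified) counts.

    FOV positions absent from ``fov_counts`` are flagged missing and later
    excluded pairwise from the registration correlation.
    """
    total = np.zeros(shape, dtype=float)
    modified = np.zeros(shape, dtype=float)
    missing = np.ones(shape, dtype=bool)
    for (r, c), (tot, mod) in fov_counts.items():
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"FOV position ({r}, {c}) outside RDM shape {shape}")
        if mod > tot:
            raise ValueError(f"FOV ({r}, {c}): modified {mod} > total {tot}")
        total[r, c], modified[r, c], missing[r, c] = tot, mod, False
    return DensityMatrix(total, modified, missing)


def _correlation_map_naive(rdm: np.ndarray, com: np.ndarray,
                           mask: np.ndarray) -> np.ndarray:
    Hr, Wr = rdm.shape
    Hc, Wc = com.shape
    out = np.full((Hc - Hr + 1, Wc - Wr + 1), np.nan)
    x = rdm[mask]
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            y = com[i:i + Hr, j:j + Wr][mask]
            if x.size < 3 or x.std() == 0 or y.std() == 0:
                continue
            out[i, j] = np.corrcoef(x, y)[0, 1]
    return out


def _correlation_map_fft(rdm: np.ndarray, com: np.ndarray,
                         mask: np.ndarray) -> np.ndarray:
    """Pearson correlation of the masked RDM with every COM subset via FFT.

    Sliding sums over the COM are cross-correlations with the (flipped)
    mask, so the whole map costs a handful of FFT convolutions.
    """
    m = mask.astype(float)
    n = m.sum()
    x = np.where(mask, rdm, 0.0)
    sx = x.sum()
    sxx = (x * x).sum()
    k_m = m[::-1, ::-1]
    k_x = x[::-1, ::-1]
    sy = fftconvolve(com, k_m, mode="valid")
    syy = fftconvolve(com * com, k_m, mode="valid")
    sxy = fftconvolve(com, k_x, mode="valid")
    cov = sxy - sx * sy / n
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
    r[(vy <= max(1e-9 * np.abs(syy).max(), 1e-12))] = np.nan
    if vx <= 1e-12 or n < 3:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def register_rdm_to_com(rdm: DensityMatrix | np.ndarray,
                        com: OccupancyMatrix | np.ndarray,
                        *,
                        z_threshold: float = 5.0,
                        method: str = "fft") -> RegistrationResult:
    """Place the RDM inside the COM by exhaustive translation search.

    The Pearson correlation between the RDM total-count grid and every
    contiguous same-shape COM subset is computed (missing FOVs excluded
    pairwise); the best offset must be an outlier of the correlation-map
    distribution (z-score >= ``z_threshold``) for the registration to be
    declared valid.  Offsets with undefined correlation (constant subset)
    are scored missing.
    """
    r = rdm.total if isinstance(rdm, DensityMatrix) else np.asarray(rdm, float)
    mask = ~rdm.missing if isinstance(rdm, DensityMatrix) else np.ones(r.shape, bool)
    c = com.counts.astype(float) if isinstance(com, OccupancyMatrix) \
        else np.asarray(com, float)
    if not (r.shape[0] < c.shape[0] and r.shape[1] < c.shape[1]):
        raise ValueError("RDM must be strictly smaller than COM in both dimensions")
    if method == "fft":
        cmap = _correlation_map_fft(r, c, mask)
    elif method == "naive":
        cmap = _correlation_map_naive(r, c, mask)
    else:
        raise ValueError(f"unknown method {method!r}")
    finite = np.isfinite(cmap)
    if not finite.any():
        raise RegistrationError("correlation undefined at every offset "
                                "(constant RDM or constant COM)")
    best_flat = np.nanargmax(cmap)
    best = np.unravel_index(best_flat, cmap.shape)
    best_val = float(cmap[best])
    vals = cmap[finite]
    sd = float(vals.std())
    z = float((best_val - vals.mean()) / sd) if sd > 0 else np.inf
    return RegistrationResult(offset=(int(best[0]), int(best[1])),
                              correlation=best_val, correlation_map=cmap,
                              z_score=z, z_threshold=z_threshold)


def link_single_cells(reg: RegistrationResult,
                      com: OccupancyMatrix,
                      cells: pd.DataFrame,
                      rdm: DensityMatrix) -> pd.DataFrame:
    """Join molecular readouts to phenotypes for registered singlet wells.

    For every RDM position whose registered COM well holds exactly one
    cell, emit one record with the well coordinates, the cell's phenotype
    and intensities, and the FOV's total / modified molecule counts.
    Empty wells and doublets are excluded; an invalid registration refuses
    to link.
    """
    if not reg.valid:
        raise RegistrationError(
            f"registration not valid (z={reg.z_score:.2f} < {reg.z_threshold}); "
            "refusing to link cells"
        )
    orow, ocol = reg.offset
    recs = []
    intensity_cols = [c for c in cells.columns
                      if c not in ("row", "col", "well_row", "well_col",
                                   "in_grid", "phenotype")]
    for i in range(rdm.shape[0]):
        for j in range(rdm.shape[1]):
            if rdm.missing[i, j]:
                continue
            wr, wc = orow + i, ocol + j
            if com.counts[wr, wc] != 1:
                continue
            sel = cells[(cells.well_row == wr) & (cells.well_col == wc)]
            rec = {"well_row": wr, "well_col": wc, "fov_row": i, "fov_col": j,
                   "total_count": int(rdm.total[i, j]),
                   "m6a_count": int(rdm.modified[i, j]),
                   "phenotype": (sel.phenotype.iloc[0]
                                 if "phenotype" in sel.columns and len(sel)
                                 else "unassigned")}
            for col in intensity_cols:
                rec[col] = float(sel[col].iloc[0]) if len(sel) else np.nan
            recs.append(rec)
    return pd.DataFrame(recs, columns=["well_row", "well_col", "fov_row",
                                       "fov_col", "phenotype", *intensity_cols,
                                       "total_count", "m6a_count"])
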