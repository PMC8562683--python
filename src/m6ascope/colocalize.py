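"""Two-channel colocalization calling and bead-based round alignment.

A molecule is called modified when a spot in the antibody channel sits
within a distance threshold of a spot in the molecule (Cy3) channel:
1 pixel (~100 nm) for modification calling in the flow-cell pipeline,
2 pixels (~200 nm) in antibody-validation mode.  Matching is one-to-one,
greedy by ascending pairwise distance, and deterministic.

Imaging rounds are aligned on fiducial beads by phase cross-correlation;
the recovered sub-pixel translation is applied to spot coordinates rather
than by resampling images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

from .spots import Image, SpotSet

__all__ = [
    "MatchResult",
    "AlignmentOffset",
    "AlignmentError",
    "match_spots",
    "detection_metrics",
    "align_rounds",
    "shift_spots",
]


@dataclass
class MatchResult:
    """One-to-one spot matches between two channels.

    ``pairs`` holds (index in A, index in B, distance in px); every index
    appears in at most one pair and every pair distance is <= ``max_dist``.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_a: list[int]
    unmatched_b: list[int]
    max_dist: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def matched_a(self) -> set[int]:
        return {i for i, _, _ in self.pairs}

    def matched_b(self) -> set[int]:
        return {j for _, j, _ in self.pairs}


class AlignmentError(RuntimeError):
    """Raised when bead-based round alignment fails its quality floor."""


@dataclass(frozen=True)
class AlignmentOffset:
    """Sub-pixel translation taking moving-round coordinates to the reference.

    ``peak_quality`` is the Pearson correlation between the reference image
    and the shifted moving image, clipped to [0, 1].
    """

    drow: float
    dcol: float
    peak_quality: float


def _coords(s) -> np.ndarray:
    if isinstance(s, SpotSet):
        return s.coordinates()
    return np.asarray(s, dtype=float).reshape(-1, 2)


def match_spots(a, b, max_dist: float = 1.0) -> MatchResult:
    """One-to-one greedy nearest matching of two spot sets.

    Candidate pairs within ``max_dist`` are sorted by ascending distance
    (ties broken on indices) and accepted greedily, so each spot matches at
    most once and mutual nearest neighbours are paired first.  Symmetric:
    swapping the inputs transposes the pair set.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    pa, pb = _coords(a), _coords(b)
    na, nb = len(pa), len(pb)
    if na == 0 or nb == 0:
        return MatchResult([], list(range(na)), list(range(nb)), max_dist)
    tree = cKDTree(pb)
    cand: list[tuple[float, int, int]] = []
    for i, neigh in enumerate(tree.query_ball_point(pa, r=max_dist)):
        for j in neigh:
            d = float(np.hypot(*(pa[i] - pb[j])))
            cand.append((d, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, d))
    pairs.sort()
    return MatchResult(
        pairs=pairs,
        unmatched_a=[i for i in range(na) if i not in used_a],
        unmatched_b=[j for j in range(nb) if j not in used_b],
        max_dist=max_dist,
    )


def detection_metrics(match: MatchResult, reference,
                      truth: np.ndarray | None = None) -> dict[str, float | None]:
    """Detection rate (and, with ground truth, sensitivity / specificity).

    The reference set is the molecule channel; its spots matched by an
    antibody-channel spot count as detected.  ``detection_rate`` is
    matched / total reference spots.  With per-reference-spot boolean
    ``truth`` labels (True = truly modified), ``sensitivity`` is the
    detection rate on truly modified spots and ``specificity`` is one minus
    the detection rate on truly unmodified spots.
    """
    n_ref = len(_coords(reference))
    out: dict[str, float | None] = {"n_reference": n_ref}
    if n_ref == 0:
        warnings.warn("empty reference spot set: detection rate undefined")
        out.update(detection_rate=None, sensitivity=None, specificity=None)
        return out
    matched = match.matched_a()
    out["detection_rate"] = len(matched) / n_ref
    out["sensitivity"] = None
    out["specificity"] = None
    if truth is not None:
        truth = np.asarray(truth, dtype=bool)
        if truth.size != n_ref:
            raise ValueError("truth labels must align with the reference set")
        pos = np.flatnonzero(truth)
        neg = np.flatnonzero(~truth)
        if pos.size:
            out["sensitivity"] = sum(1 for i in pos if i in matched) / pos.size
        if neg.size:
            out["specificity"] = 1.0 - sum(1 for i in neg if i in matched) / neg.size
    return out


def align_rounds(moving, reference, *, upsample_factor: int = 50,
                 quality_floor: float = 0.05) -> AlignmentOffset:
    """Sub-pixel translation aligning a moving round to the reference round.

    Both images should show the fiducial-bead channel.  The returned
    ``(drow, dcol)`` is the shift to ADD to moving-round spot coordinates to
    express them in the reference frame.  Raises :class:`AlignmentError`
    when the post-alignment correlation falls below ``quality_floor``
    (e.g. a blank round).
    """
    mov = moving.pixels if isinstance(moving, Image) else np.asarray(moving, float)
    ref = reference.pixels if isinstance(reference, Image) else np.asarray(reference, float)
    if mov.shape != ref.shape:
        raise ValueError("round images must share a shape")
    if np.array_equal(mov, ref):
        return AlignmentOffset(0.0, 0.0, 1.0)
    shift, _, _ = phase_cross_correlation(ref, mov,
                                          upsample_factor=upsample_factor)
    drow, dcol = float(shift[0]), float(shift[1])
    # quality: Pearson correlation after applying the integer part of the shift
    ir, ic = int(round(drow)), int(round(dcol))
    shifted = np.roll(np.roll(mov, ir, axis=0), ic, axis=1)
    rs, cs = abs(ir), abs(ic)
    core_r = slice(rs, ref.shape[0] - rs) if rs else slice(None)
    core_c = slice(cs, ref.shape[1] - cs) if cs else slice(None)
    x = ref[core_r, core_c].ravel()
    y = shifted[core_r, core_c].ravel()
    if x.size < 4 or x.std() == 0 or y.std() == 0:
        quality = 0.0
    else:
        quality = float(np.clip(np.corrcoef(x, y)[0, 1], 0.0, 1.0))
    if quality < quality_floor:
        rnd = moving.round if isinstance(moving, Image) else "?"
        raise AlignmentError(
            f"alignment of round {rnd} failed: correlation {quality:.3f} "
            f"below floor {quality_floor}"
        )
    return AlignmentOffset(drow, dcol, quality)


def shift_spots(spotset: SpotSet, offset: AlignmentOffset) -> SpotSet:
    """Return a copy of ``spotset`` with the alignment offset applied."""
    from dataclasses import replace

    moved = [replace(s, row=s.row + offset.drow, col=s.col + offset.dcol)
             for s in spotset.spots]
    return SpotSet(spots=moved, channel=spotset.channel, round=spotset.round,
                   shape=spotset.shape)
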