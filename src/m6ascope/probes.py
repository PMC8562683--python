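"""seqFISH primary / readout probe design as a deterministic sequence pipeline.

For each gene an exon-consensus mRNA sequence is scanned for 25-30 nt
candidate windows, filtered on GC content (45-70% inclusive), homopolymer
runs (no 5+ consecutive identical bases) and spacing (>= 2 nt gap between
adjacent probe footprints).  Cross-hybridization between probe sets is
suppressed by removing any probe sharing an exact substring of 17 nt or
longer with another probe (either strand); sets larger than 32 probes are
trimmed toward the 55% GC target.  Readout sequences (20 nt) are screened
against a reference transcript set for contiguous homology longer than
14 nt.  Primary oligos are assembled as hybridizing target sequence +
"TA" gap + reverse complement of the gene's readout.

Exact-substring matching deliberately replaces BLAST for the 17-nt and
15-nt rules: at these lengths an ungapped, mismatch-free seed is exactly
what a short-word BLAST hit reports, and the substring test is
deterministic and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "ProbeCandidate",
    "ProbeSet",
    "PrimaryProbe",
    "gc_percent",
    "max_homopolymer_run",
    "extract_candidates",
    "cross_hyb_filter",
    "trim_set",
    "filter_readouts",
    "assemble_primary_probes",
    "design_probes",
    "verify_probe_set",
]

GC_BOUNDS = (45.0, 70.0)
MAX_RUN = 4           # longest allowed homopolymer
LENGTHS = (25, 30)    # inclusive probe length range
MIN_GAP = 2           # nt of clear sequence between adjacent probe footprints
CROSS_HYB_K = 17      # shared-substring length that disqualifies a probe
READOUT_MAX_HOMOLOGY = 14  # longest tolerated contiguous match to the reference
MAX_SET_SIZE = 32
MIN_SET_SIZE = 20
GC_TARGET = 55.0


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * sum(1 for b in s if b in "GC") / len(s)


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for b in seq.upper():
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


@dataclass(frozen=True)
class ProbeCandidate:
    """A candidate hybridization window on the mRNA consensus (0-based, half-open)."""

    gene: str
    start: int
    end: int
    sequence: str
    gc: float

    def __post_init__(self) -> None:
        if not (LENGTHS[0] <= len(self.sequence) <= LENGTHS[1]):
            raise ValueError("probe length outside the 25-30 nt range")
        if self.end - self.start != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeSet:
    """Ordered probes for one gene, with bookkeeping of dropped candidates."""

    gene: str
    probes: list[ProbeCandidate] = field(default_factory=list)
    n_windows: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def undersized(self) -> bool:
        return len(self.probes) < MIN_SET_SIZE

    @property
    def oversized_flag(self) -> bool:
        """Sets of 31-32 probes exceed the 20-30 design target but pass the trim cap."""
        return len(self.probes) > 30


@dataclass(frozen=True)
class PrimaryProbe:
    """Assembled primary oligo: hybridizing target + 'TA' + revcomp(readout)."""

    gene: str
    target: str
    readout: str
    start: int
    end: int

    @property
    def gap(self) -> str:
        return "TA"

    @property
    def full_sequence(self) -> str:
        return self.target + "TA" + revcomp(self.readout)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def extract_candidates(
    gene: str,
    consensus: str,
    *,
    gc_bounds: tuple[float, float] = GC_BOUNDS,
    max_run: int = MAX_RUN,
    lengths: tuple[int, int] = LENGTHS,
    min_gap: int = MIN_GAP,
) -> ProbeSet:
    """Enumerate and select non-conflicting probe windows on a consensus.

    All windows with length in ``lengths`` (inclusive) are enumerated; those
    with GC outside ``gc_bounds`` (inclusive bounds), a homopolymer run
    longer than ``max_run``, or ambiguous bases are dropped.  A deterministic
    greedy left-to-right scan then selects windows whose footprints are
    separated by at least ``min_gap`` nt; at each feasible start the window
    whose GC is closest to the 55% target is taken (shorter window on ties).
    """
    seq = _normalize(consensus)
    lo, hi = lengths
    if len(seq) < lo:
        raise ValueError("consensus shorter than the minimum probe length")
    n_windows = 0
    n_gc = n_run = n_ambig = 0
    viable: dict[int, list[ProbeCandidate]] = {}
    for start in range(len(seq) - lo + 1):
        for L in range(lo, hi + 1):
            end = start + L
            if end > len(seq):
                break
            n_windows += 1
            w = seq[start:end]
            if any(b not in "ACGT" for b in w):
                n_ambig += 1
                continue
            g = gc_percent(w)
            if not (gc_bounds[0] <= g <= gc_bounds[1]):
                n_gc += 1
                continue
            if max_homopolymer_run(w) > max_run:
                n_run += 1
                continue
            viable.setdefault(start, []).append(
                ProbeCandidate(gene, start, end, w, g))
    chosen: list[ProbeCandidate] = []
    next_free = 0
    for start in sorted(viable):
        if start < next_free:
            continue
        cands = sorted(viable[start],
                       key=lambda p: (abs(p.gc - GC_TARGET), p.length))
        pick = cands[0]
        chosen.append(pick)
        next_free = pick.end + min_gap
    return ProbeSet(gene=gene, probes=chosen, n_windows=n_windows,
                    dropped={"gc": n_gc, "homopolymer": n_run,
                             "ambiguous": n_ambig})


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i:i + k]


def cross_hyb_filter(sets: list[ProbeSet],
                     min_match: int = CROSS_HYB_K) -> list[ProbeSet]:
    """Drop probes sharing an exact >= ``min_match`` nt substring with another probe.

    Matches on either strand count, within a set or across sets.  Probes are
    scanned in deterministic order (input set order, then ascending start);
    of a matched pair the later probe is dropped, so earlier-designed probes
    survive.
    """
    if not sets:
        raise ValueError("need at least one probe set")
    index: set[str] = set()
    out: list[ProbeSet] = []
    for ps in sets:
        kept: list[ProbeCandidate] = []
        n_dropped = 0
        for probe in sorted(ps.probes, key=lambda p: p.start):
            fwd = list(_kmers(probe.sequence, min_match))
            rev = list(_kmers(revcomp(probe.sequence), min_match))
            if any(k in index for k in fwd + rev):
                n_dropped += 1
                continue
            kept.append(probe)
            index.update(fwd)
            index.update(rev)
        dropped = dict(ps.dropped)
        dropped["cross_hyb"] = dropped.get("cross_hyb", 0) + n_dropped
        out.append(ProbeSet(gene=ps.gene, probes=kept,
                            n_windows=ps.n_windows, dropped=dropped))
    return out


def trim_set(ps: ProbeSet, max_size: int = MAX_SET_SIZE,
             gc_target: float = GC_TARGET) -> ProbeSet:
    """Trim oversize sets by removing probes farthest from the GC target.

    While the set exceeds ``max_size``, the probe maximizing |gc - target|
    is removed; ties go to the larger start coordinate.  Sets at or under
    the cap are returned unchanged.
    """
    probes = list(ps.probes)
    n_trimmed = 0
    while len(probes) > max_size:
        worst = max(probes, key=lambda p: (abs(p.gc - gc_target), p.start))
        probes.remove(worst)
        n_trimmed += 1
    if n_trimmed == 0:
        return ps
    dropped = dict(ps.dropped)
    dropped["gc_trim"] = dropped.get("gc_trim", 0) + n_trimmed
    return ProbeSet(gene=ps.gene, probes=probes, n_windows=ps.n_windows,
                    dropped=dropped)


def filter_readouts(readouts: dict[str, str], reference: list[str],
                    max_homology: int = READOUT_MAX_HOMOLOGY) -> dict[str, str]:
    """Keep readouts with no contiguous reference match longer than ``max_homology``.

    A 20-nt readout is dropped if any of its substrings of length
    ``max_homology + 1`` occurs exactly in a reference transcript or its
    reverse complement.
    """
    k = max_homology + 1
    ref_index: set[str] = set()
    for seq in reference:
        s = _normalize(seq)
        ref_index.update(_kmers(s, k))
        ref_index.update(_kmers(revcomp(s), k))
    kept = {}
    for name, seq in readouts.items():
        s = _normalize(seq)
        if len(s) != 20:
            raise ValueError(f"readout {name!r} must be 20 nt (got {len(s)})")
        if any(sub in ref_index for sub in _kmers(s, k)):
            continue
        kept[name] = s
    return kept


def assemble_primary_probes(ps: ProbeSet, readout: str) -> list[PrimaryProbe]:
    """Assemble full primary oligos for one gene.

    The hybridizing part is the reverse complement of the consensus window
    (probes must anneal to the mRNA sense sequence); the gene's readout
    site is appended as revcomp(readout) behind a 'TA' gap.
    """
    readout = _normalize(readout)
    return [
        PrimaryProbe(gene=ps.gene, target=revcomp(p.sequence),
                     readout=readout, start=p.start, end=p.end)
        for p in ps.probes
    ]


def design_probes(
    consensi: dict[str, str],
    readouts: dict[str, str],
    reference: list[str] | None = None,
    **params,
) -> tuple[dict[str, list[PrimaryProbe]], list[ProbeSet]]:
    """Full design pipeline: candidates -> cross-hyb filter -> trim -> assemble.

    ``consensi`` maps gene -> exon-consensus mRNA sequence; ``readouts``
    maps readout id -> 20-nt sequence, assigned to genes in input order
    after reference screening.  Returns the assembled oligos per gene and
    the final (filtered, trimmed) probe sets.
    """
    sets = [extract_candidates(g, seq, **params) for g, seq in consensi.items()]
    sets = cross_hyb_filter(sets)
    sets = [trim_set(ps) for ps in sets]
    kept_readouts = filter_readouts(readouts, reference or [])
    if len(kept_readouts) < len(sets):
        raise ValueError(
            f"only {len(kept_readouts)} readouts survive reference screening "
            f"for {len(sets)} genes"
        )
    oligos: dict[str, list[PrimaryProbe]] = {}
    for ps, rname in zip(sets, kept_readouts):
        oligos[ps.gene] = assemble_primary_probes(ps, kept_readouts[rname])
    return oligos, sets


def verify_probe_set(sets: list[ProbeSet],
                     *,
                     gc_bounds: tuple[float, float] = GC_BOUNDS,
                     max_run: int = MAX_RUN,
                     min_gap: int = MIN_GAP,
                     min_match: int = CROSS_HYB_K) -> list[str]:
    """Independent re-check of every design rule on emitted sets.

    Returns a list of human-readable violations (empty means sound):
    GC bounds, homopolymer runs, footprint spacing within each set, and
    all-pairs shared-substring search (brute force, either strand) across
    every emitted probe.
    """
    problems: list[str] = []
    for ps in sets:
        ordered = sorted(ps.probes, key=lambda p: p.start)
        for p in ordered:
            if not (gc_bounds[0] <= gc_percent(p.sequence) <= gc_bounds[1]):
                problems.append(f"{ps.gene}:{p.start} GC {p.gc:.1f} out of bounds")
            if max_homopolymer_run(p.sequence) > max_run:
                problems.append(f"{ps.gene}:{p.start} homopolymer run > {max_run}")
        for a, b in zip(ordered, ordered[1:]):
            if b.start - a.end < min_gap:
                problems.append(
                    f"{ps.gene}: probes at {a.start} and {b.start} closer than "
                    f"{min_gap} nt")
    flat = [(ps.gene, p) for ps in sets for p in ps.probes]
    for i, (ga, a) in enumerate(flat):
        for gb, b in flat[i + 1:]:
            if _longest_shared_substring(a.sequence, b.sequence) >= min_match:
                problems.append(f"cross-hyb: {ga}:{a.start} vs {gb}:{b.start}")
    return problems


def _longest_shared_substring(a: str, b: str) -> int:
    """Brute-force longest exact shared substring length, either strand of b."""
    best = 0
    for bb in (b, revcomp(b)):
        # dynamic programming over suffix matches
        prev = [0] * (len(bb) + 1)
        for ca in a:
            cur = [0] * (len(bb) + 1)
            for j, cb in enumerate(bb, 1):
                if ca == cb:
                    cur[j] = prev[j - 1] + 1
                    best = max(best, cur[j])
            prev = cur
    return best
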