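"""In-vitro transcription (IVT) model with fractional m6ATP incorporation.

T7 RNA polymerase run-off transcription of a DNA template oligo: the
transcript starts at the first base downstream of the 17-nt T7 promoter
(TAATACGACTCACTATA) and runs to the template 3' end.  During synthesis a
fraction of the ATP pool is replaced with N6-methyladenosine-5'-triphosphate
(m6ATP), so each templated adenosine is independently methylated with that
probability.  A post-transcriptional polyA tail (added enzymatically with
unmodified ATP) is never methylated.

The module ships the 197-nt validation template used to characterise the
anti-m6A antibody; at a 50% m6ATP fraction its run-off transcript carries
an expected 12 methylated adenosines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "T7_PROMOTER",
    "IVT_TEMPLATE",
    "SimulatedTranscript",
    "runoff_transcript",
    "simulate_ivt",
    "expected_modified_count",
]

#: Canonical 17-nt T7 promoter (sense strand, transcription starts at the next base).
T7_PROMOTER = "TAATACGACTCACTATA"

#: 197-nt DNA oligo (sense strand, T7 promoter embedded) used for antibody
#: validation IVTs.
IVT_TEMPLATE = (
    "GGCCAGTGAATTGTAATACGACTCACTATAGGGAGGCGGTAACACCTTCTGGACTCTTCATAGAGT"
    "TGGTCTATTTGTCTCCACGCTGCCAGGTTGTTGTGGCCTGTTTTCGGGCGTCTGCGGCGAAGATCT"
    "CTTGTCAGAGCCTTAGGTGTATCTAGATTGTGATCCCCTTTCCTCACTTGGTAGTCTGTCGACTT"
)


class PromoterError(ValueError):
    """The promoter is absent from, or ambiguous in, the template."""


@dataclass(frozen=True)
class SimulatedTranscript:
    """A single simulated IVT product.

    Attributes
    ----------
    sequence
        RNA sequence (ACGU alphabet), including the polyA tail if present.
    modified_positions
        Strictly increasing 0-based indices of m6A bases; every index points
        at an adenosine in the transcribed (non-tail) region.
    has_polya_tail
        Whether a polyA tail was appended after transcription.
    """

    sequence: str
    modified_positions: tuple[int, ...] = field(default_factory=tuple)
    has_polya_tail: bool = False

    def __post_init__(self) -> None:
        pos = self.modified_positions
        if any(b - a <= 0 for a, b in zip(pos, pos[1:])):
            raise ValueError("modified positions must be strictly increasing")
        for p in pos:
            if not (0 <= p < len(self.sequence)) or self.sequence[p] != "A":
                raise ValueError(f"modified position {p} is not an adenosine")


def _transcribe(dna: str) -> str:
    return dna.upper().replace("T", "U")


def runoff_transcript(template: str, promoter: str = T7_PROMOTER) -> str:
    """Return the RNA run-off transcript of a sense-strand DNA template.

    The transcript begins at the first base after the promoter's 3' end and
    extends to the template 3' end.

    Raises
    ------
    PromoterError
        If the promoter occurs zero or more than one time in the template.
    """
    template = template.upper().replace("U", "T")
    promoter = promoter.upper().replace("U", "T")
    n = template.count(promoter)
    if n == 0:
        raise PromoterError(f"promoter {promoter!r} not found in template")
    if n > 1:
        raise PromoterError(f"promoter {promoter!r} occurs {n} times in template")
    start = template.index(promoter) + len(promoter)
    if start >= len(template):
        raise PromoterError("promoter lies at the template 3' end; empty run-off")
    return _transcribe(template[start:])


def expected_modified_count(
    template: str,
    promoter: str = T7_PROMOTER,
    m6atp_fraction: float = 0.5,
) -> float:
    """Expected number of m6A bases per run-off transcript.

    Each templated adenosine is methylated independently with probability
    ``m6atp_fraction``, so the expectation is (adenosine count of the run-off
    transcript) x fraction.  The polyA tail never enters this count.
    """
    if not 0.0 <= m6atp_fraction <= 1.0:
        raise ValueError("m6atp_fraction must be in [0, 1]")
    rna = runoff_transcript(template, promoter)
    return rna.count("A") * m6atp_fraction


def simulate_ivt(
    template: str,
    promoter: str = T7_PROMOTER,
    m6atp_fraction: float = 0.5,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
    polya_tail_length: int = 0,
) -> list[SimulatedTranscript]:
    """Simulate ``n`` run-off transcripts with fractional m6ATP incorporation.

    Parameters
    ----------
    template, promoter
        Sense-strand DNA oligo and promoter; the promoter must occur exactly
        once.
    m6atp_fraction
        Probability that each templated adenosine is m6A.
    n
        Number of transcripts.
    seed
        Seed or ``numpy.random.Generator`` for reproducibility.
    polya_tail_length
        If > 0, append that many unmodified A bases (enzymatic tailing with
        100% ATP).
    """
    if not 0.0 <= m6atp_fraction <= 1.0:
        raise ValueError("m6atp_fraction must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be non-negative")
    rna = runoff_transcript(template, promoter)
    a_idx = np.flatnonzero(np.frombuffer(rna.encode(), dtype=np.uint8) == ord("A"))
    rng = np.random.default_rng(seed)
    tail = "A" * polya_tail_length
    out = []
    for _ in range(n):
        if m6atp_fraction == 0.0 or a_idx.size == 0:
            mods: tuple[int, ...] = ()
        else:
            hit = rng.random(a_idx.size) < m6atp_fraction
            mods = tuple(int(i) for i in a_idx[hit])
        out.append(
            SimulatedTranscript(
                sequence=rna + tail,
                modified_positions=mods,
                has_polya_tail=polya_tail_length > 0,
            )
        )
    return out
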