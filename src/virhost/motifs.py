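"""Terminal consensus motifs on segmented genomes.

Segmented negative-strand RNA viruses (tenuiviruses and relatives) carry a
conserved ~9-nt sequence at both ends of every genome segment; the 5' and 3'
consensus are mutually reverse-complementary, allowing the termini to base
pair into a panhandle.  Finding the consensus at every segment end is
evidence that full-length segments were assembled.

Two consensus presets ship for the 3' end: the canonical pair
(5'-ACACAAAGU / ACUUUGUGU-3', perfectly self-complementary) and a one-base
variant (ACUUUGAGU) observed on some assemblies; neither is silently
preferred — the preset name is always echoed in output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import ValidationError

__all__ = [
    "MOTIF_PRESETS",
    "Segment",
    "SegmentedGenome",
    "MotifHit",
    "ScanError",
    "scan_termini",
    "panhandle_check",
    "extract_cds",
    "reverse_complement",
]

#: named 5'/3' consensus pairs (RNA alphabet; U==T internally)
MOTIF_PRESETS: dict[str, tuple[str, str]] = {
    "canonical": ("ACACAAAGU", "ACUUUGUGU"),
    "variant_a": ("ACACAAAGU", "ACUUUGAGU"),
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement; accepts RNA or DNA, returns the input alphabet."""
    is_rna = "U" in seq.upper()
    out = _norm(seq).translate(_COMPLEMENT)[::-1]
    return out.replace("T", "U") if is_rna else out


@dataclass(frozen=True)
class Segment:
    segment_id: str
    sequence: str
    complete_ends: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"segment {self.segment_id!r}: empty sequence")


@dataclass
class SegmentedGenome:
    virus_id: str
    segments: list[Segment]


@dataclass(frozen=True)
class MotifHit:
    segment_id: str
    end: str  # five_prime | three_prime
    matched_window: str
    mismatch_positions: tuple[int, ...]  # 1-based offsets within the motif

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass(frozen=True)
class ScanError:
    """Per-segment problem encountered while scanning (scan continues)."""

    segment_id: str
    message: str


def _hamming_positions(window: str, motif: str) -> tuple[int, ...]:
    return tuple(i + 1 for i, (a, b) in enumerate(zip(window, motif)) if a != b)


def scan_termini(
    genome: SegmentedGenome,
    motif5: str,
    motif3: str,
    max_mismatch: int = 0,
    skip_incomplete_ends: bool = False,
) -> tuple[list[MotifHit], list[ScanError]]:
    """Anchor both motifs at the segment termini and report near-matches.

    ``motif5`` is compared against the first ``len(motif5)`` bases of each
    segment and ``motif3`` against the last ``len(motif3)`` bases (both
    written 5'->3'; U and T are equivalent).  A hit is emitted when the
    Hamming distance is at most ``max_mismatch``, with 1-based mismatch
    offsets within the motif.  Segments shorter than a motif produce a
    per-segment error record and scanning continues.
    """
    if len(motif5) < 4 or len(motif3) < 4:
        raise ValidationError("motifs must be at least 4 nt")
    m5, m3 = _norm(motif5), _norm(motif3)
    hits: list[MotifHit] = []
    errors: list[ScanError] = []
    for seg in genome.segments:
        if skip_incomplete_ends and not seg.complete_ends:
            continue
        s = _norm(seg.sequence)
        if len(s) < max(len(m5), len(m3)):
            errors.append(
                ScanError(seg.segment_id, f"segment shorter than motif ({len(s)} nt)")
            )
            continue
        for end, motif, window_raw in (
            ("five_prime", m5, seg.sequence[: len(m5)]),
            ("three_prime", m3, seg.sequence[-len(m3):]),
        ):
            window = _norm(window_raw)
            mism = _hamming_positions(window, motif)
            if len(mism) <= max_mismatch:
                hits.append(
                    MotifHit(
                        segment_id=seg.segment_id,
                        end=end,
                        matched_window=window_raw,
                        mismatch_positions=mism,
                    )
                )
    return hits, errors


def panhandle_check(motif5: str, motif3: str) -> dict[str, object]:
    """Is the 3' consensus the reverse complement of the 5' consensus?

    Reports position-wise differences between ``motif3`` and
    ``reverse_complement(motif5)`` — a perfect panhandle has zero.
    """
    if len(motif5) != len(motif3):
        raise ValidationError("motifs must have equal length")
    expected = _norm(reverse_complement(motif5))
    got = _norm(motif3)
    mism = _hamming_positions(got, expected)
    return {"complementary": len(mism) == 0, "mismatches": len(mism), "positions": mism}


def extract_cds(sequence: str, start: int, end: int, strand: str = "plus") -> str:
    """Extract a coding region by 1-based inclusive coordinates.

    ``strand="minus"`` returns the reverse complement — ambisense segments
    encode proteins on both orientations, so minus-strand ORFs must be
    flipped before codon analysis.
    """
    if strand not in ("plus", "minus"):
        raise ValidationError(f"unknown strand {strand!r}")
    if not (1 <= start <= end <= len(sequence)):
        raise ValidationError(
            f"coordinates ({start}, {end}) out of range for length {len(sequence)}"
        )
    sub = sequence[start - 1 : end]
    return reverse_complement(sub) if strand == "minus" else sub
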