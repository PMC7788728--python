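"""Synthetic-data generators: count tables with prescribed abundances,
CDS sets with controlled composition, and segmented genomes with planted
terminal motifs.

These generators produce the standard pipeline inputs with known ground
truth, so every analysis stage can be validated by parameter recovery:
abundances round-trip within quantization error, planted codon/dinucleotide
regimes separate in PCA, and planted terminal mismatches are reported
exactly.  All randomness is seeded; identical seeds give identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .composition import BASES, CODONS
from .io import CountTable, Library, ValidationError
from .motifs import Segment, SegmentedGenome, _norm

__all__ = [
    "AbundanceSpec",
    "GroupSpec",
    "CompositionSpec",
    "gen_count_table",
    "gen_cds_set",
    "gen_segmented_genome",
]


@dataclass
class AbundanceSpec:
    """Target abundance percentages per (feature, library).

    Absent (feature, library) pairs stay absent in the generated table and
    load as not-detected.  ``mode="exact"`` rounds ``target% x total / 100``
    to the nearest count, so recomputed percentages match targets within
    ``100 / (2 x total)`` percentage points; ``mode="multinomial"`` draws
    counts with the target probabilities (unassigned mass goes to an
    implicit host/background bucket that is not emitted).
    """

    libraries: list[Library]
    targets: dict[tuple[str, str], float]  # (feature_id, library_id) -> percent
    feature_kind: dict[str, str]
    mode: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        per_lib: dict[str, float] = {}
        for (feat, lib), pct in self.targets.items():
            if pct < 0:
                raise ValidationError(f"negative target for ({feat!r}, {lib!r})")
            per_lib[lib] = per_lib.get(lib, 0.0) + pct
        for lib, s in per_lib.items():
            if s > 100.0 + 1e-9:
                raise ValidationError(f"library {lib!r}: targets sum to {s}% > 100%")
        if self.mode not in ("exact", "multinomial"):
            raise ValidationError(f"unknown mode {self.mode!r}")


def gen_count_table(spec: AbundanceSpec) -> CountTable:
    """Materialize a count table realizing an abundance spec."""
    counts: dict[tuple[str, str], int] = {}
    totals = {lib.library_id: lib.total_reads for lib in spec.libraries}
    if spec.mode == "exact":
        for (feat, lib), pct in spec.targets.items():
            counts[(feat, lib)] = int(round(pct * totals[lib] / 100.0))
    else:
        rng = np.random.default_rng(spec.seed)
        for lib in spec.libraries:
            feats = sorted(f for (f, l) in spec.targets if l == lib.library_id)
            if not feats:
                continue
            probs = np.array(
                [spec.targets[(f, lib.library_id)] / 100.0 for f in feats]
            )
            rest = 1.0 - probs.sum()
            draw = rng.multinomial(lib.total_reads, np.append(probs, rest))
            for f, n in zip(feats, draw[:-1]):
                counts[(f, lib.library_id)] = int(n)
    return CountTable(
        libraries=list(spec.libraries),
        counts=counts,
        feature_kind=dict(spec.feature_kind),
    )


@dataclass
class GroupSpec:
    """One group of CDS with a common codon-usage regime.

    ``codon_weights`` are relative sampling weights over the 64 codons
    (normalized internally); ``dinucleotide_tilt`` optionally multiplies the
    acceptance probability of a candidate codon by the tilt of every
    dinucleotide it introduces (its two internal ones plus the junction with
    the previous codon), applied by rejection sampling.
    """

    label: str
    n_sequences: int
    length: int
    codon_weights: Mapping[str, float]
    dinucleotide_tilt: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.length % 3 != 0:
            raise ValidationError(f"group {self.label!r}: length must be a multiple of 3")
        w = np.array([self.codon_weights.get(c, 0.0) for c in CODONS], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValidationError(f"group {self.label!r}: weights not normalizable")


@dataclass
class CompositionSpec:
    groups: list[GroupSpec]
    seed: int = 0


def _sample_cds(rng: np.random.Generator, group: GroupSpec) -> str:
    w = np.array([group.codon_weights.get(c, 0.0) for c in CODONS], dtype=float)
    p = w / w.sum()
    n_codons = group.length // 3
    tilt = group.dinucleotide_tilt
    if not tilt:
        idx = rng.choice(64, size=n_codons, p=p)
        return "".join(CODONS[i] for i in idx)
    tmax = max(max(tilt.values()), 1.0)
    parts: list[str] = []
    prev_last = ""
    for _ in range(n_codons):
        while True:
            codon = CODONS[rng.choice(64, p=p)]
            dinucs = [codon[0:2], codon[1:3]]
            if prev_last:
                dinucs.append(prev_last + codon[0])
            accept = 1.0
            for d in dinucs:
                accept *= tilt.get(d, 1.0) / tmax
            if rng.random() < accept:
                parts.append(codon)
                prev_last = codon[-1]
                break
    return "".join(parts)


def gen_cds_set(spec: CompositionSpec):
    """Generate labelled CDS records drawn codon-by-codon from group weights.

    Returns ``(records, labels)`` where ``records`` is a list of Biopython
    ``SeqRecord`` and ``labels`` maps sequence id to group label, in
    generation order.  Empirical codon frequencies converge to the weights
    as length grows.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    records: list[SeqRecord] = []
    rows = []
    for group in spec.groups:
        for i in range(group.n_sequences):
            seq_id = f"{group.label}_{i + 1}"
            seq = _sample_cds(rng, group)
            records.append(SeqRecord(Seq(seq), id=seq_id, description=""))
            rows.append({"sequence_id": seq_id, "group_label": group.label})
    return records, pd.DataFrame(rows, columns=["sequence_id", "group_label"])


def gen_segmented_genome(
    n_segments: int,
    lengths: Sequence[int],
    motif5: str,
    motif3: str,
    mismatches_per_segment: Sequence[int | tuple[int, int]] | None = None,
    seed: int = 0,
    virus_id: str = "synthetic_virus",
) -> SegmentedGenome:
    """Random segments whose termini carry the motifs with planted mismatches.

    ``mismatches_per_segment`` gives, per segment, either one integer
    (applied to both ends) or a ``(five_prime, three_prime)`` pair.  The
    planted substitutions land at seeded positions within the motif and
    always change the base, so a scanner must report exactly that many
    mismatches.  Different seeds change the interiors but never the termini.
    """
    if len(lengths) != n_segments:
        raise ValidationError("one length per segment required")
    mism = list(mismatches_per_segment or [0] * n_segments)
    if len(mism) != n_segments:
        raise ValidationError("one mismatch count per segment required")
    m5, m3 = _norm(motif5), _norm(motif3)
    rng = np.random.default_rng(seed)
    # interiors drawn from a seed stream independent of the mismatch stream,
    # so termini are identical across seeds only in the planted sense
    mut_rng = np.random.default_rng(2**20 + 7)  # fixed: termini depend only on request
    segments = []
    for i, (length, mm) in enumerate(zip(lengths, mism)):
        if length < len(m5) + len(m3):
            raise ValidationError(f"segment {i + 1}: length {length} too short for motifs")
        n5, n3 = (mm, mm) if isinstance(mm, int) else mm
        if n5 > len(m5) or n3 > len(m3):
            raise ValidationError(f"segment {i + 1}: more mismatches than motif positions")
        five = _plant(mut_rng, m5, n5)
        three = _plant(mut_rng, m3, n3)
        interior = "".join(
            BASES[j] for j in rng.integers(0, 4, size=length - len(m5) - len(m3))
        )
        segments.append(
            Segment(segment_id=f"{virus_id}_seg{i + 1}", sequence=five + interior + three)
        )
    return SegmentedGenome(virus_id=virus_id, segments=segments)


def _plant(rng: np.random.Generator, motif: str, n_mismatches: int) -> str:
    out = list(motif)
    positions = rng.choice(len(motif), size=n_mismatches, replace=False)
    for pos in positions:
        alternatives = [b for b in BASES if b != motif[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)
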