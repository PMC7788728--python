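"""Abundance percentages, fold-changes and normalized segment shares.

Abundance of a feature in a library is the percentage of the library's reads
assigned to it: ``100 * reads / total_reads``.  A multipartite virus's
whole-genome abundance is the sum of its segments' percentages.  Normalized
segment shares divide each segment's abundance by that whole-genome total,
so shares within a (virus, library) pair sum to one — the quantity used to
assess asymmetric accumulation of genome segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping

import pandas as pd

from .io import CountTable, ValidationError, VirusMeta

__all__ = [
    "AbundanceTable",
    "SegmentShareTable",
    "compute_abundance",
    "fold_vs_gene",
    "format_fold",
    "segment_shares",
]


@dataclass
class AbundanceTable:
    """Percentages of library reads per feature, with detection encoded.

    ``detected[(feature, library)]`` is False when the feature was absent
    from the library (no reads, or a missing cell in a percentage-mode
    table).  ``value`` returns 0.0 for undetected pairs.
    """

    values: dict[tuple[str, str], float]
    detected: dict[tuple[str, str], bool]
    feature_ids: list[str] = field(default_factory=list)
    library_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (feat, lib), v in self.values.items():
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"abundance for ({feat!r}, {lib!r}) out of [0, 100]: {v}"
                )
        if not self.feature_ids:
            self.feature_ids = sorted({f for f, _ in self.values})
        if not self.library_ids:
            self.library_ids = sorted({l for _, l in self.values})

    def value(self, feature_id: str, library_id: str) -> float:
        return self.values.get((feature_id, library_id), 0.0)

    def is_detected(self, feature_id: str, library_id: str) -> bool:
        return self.detected.get((feature_id, library_id), False)

    def detected_libraries(self, feature_id: str) -> list[str]:
        """Libraries where the feature is present, in table order."""
        return [l for l in self.library_ids if self.is_detected(feature_id, l)]

    def detected_values(self, feature_id: str) -> list[float]:
        return [self.value(feature_id, l) for l in self.detected_libraries(feature_id)]

    def to_frame(self, not_detected: str = "-") -> pd.DataFrame:
        """Wide features x libraries table with a marker for absent cells."""
        data = {
            lib: [
                self.value(f, lib) if self.is_detected(f, lib) else not_detected
                for f in self.feature_ids
            ]
            for lib in self.library_ids
        }
        df = pd.DataFrame(data, index=pd.Index(self.feature_ids, name="feature_id"))
        return df


@dataclass
class SegmentShareTable:
    """Per-library fraction of whole-genome abundance on each segment."""

    shares: dict[tuple[str, str], float]
    segment_ids: list[str]
    library_ids: list[str]

    def share(self, segment_id: str, library_id: str) -> float:
        return self.shares[(segment_id, library_id)]

    def median_shares(self) -> dict[str, float]:
        """Median share per segment across the libraries present."""
        return {
            seg: median(
                self.shares[(seg, lib)]
                for lib in self.library_ids
                if (seg, lib) in self.shares
            )
            for seg in self.segment_ids
        }

    def to_frame(self) -> pd.DataFrame:
        data = {
            lib: [self.shares.get((s, lib), float("nan")) for s in self.segment_ids]
            for lib in self.library_ids
        }
        return pd.DataFrame(data, index=pd.Index(self.segment_ids, name="segment_id"))


def compute_abundance(
    table: CountTable, viruses: Iterable[VirusMeta] = ()
) -> AbundanceTable:
    """Percent of each library's reads per feature; virus totals added.

    For every virus in ``viruses`` a whole-virus row (keyed by ``virus_id``)
    is added whose value is the sum of its segments' percentages; it is
    detected wherever any segment is.  A single-segment virus whose segment
    id equals the virus id simply keeps that row.
    """
    for lib in table.libraries:
        if lib.total_reads == 0:
            raise ValidationError(
                f"library {lib.library_id!r} has total_reads == 0; "
                "abundance undefined"
            )
    values: dict[tuple[str, str], float] = {}
    detected: dict[tuple[str, str], bool] = {}
    lib_ids = table.library_ids
    feats = table.feature_ids
    totals = {lib.library_id: lib.total_reads for lib in table.libraries}
    for feat in feats:
        for lib in lib_ids:
            n = table.count(feat, lib)
            if n > 0:
                values[(feat, lib)] = 100.0 * n / totals[lib]
                detected[(feat, lib)] = True
            else:
                detected[(feat, lib)] = False

    order = list(feats)
    for v in viruses:
        for lib in lib_ids:
            segs_present = [s for s in v.segment_ids if detected.get((s, lib), False)]
            if segs_present:
                values[(v.virus_id, lib)] = sum(values[(s, lib)] for s in segs_present)
                detected[(v.virus_id, lib)] = True
            else:
                detected.setdefault((v.virus_id, lib), False)
        if v.virus_id not in order:
            order.append(v.virus_id)
    return AbundanceTable(values=values, detected=detected, feature_ids=order, library_ids=lib_ids)


def fold_vs_gene(abundance_virus: float, abundance_gene: float) -> float:
    """Ratio of a virus's abundance to a reference gene's (dimensionless)."""
    if abundance_gene <= 0:
        raise ValidationError(
            "fold-change undefined: reference gene abundance must be > 0"
        )
    return abundance_virus / abundance_gene


def format_fold(fold: float) -> str:
    """Presentation rounding for fold-ratios.

    Ratios of ten or more are shown to the nearest integer; ratios below one
    to three decimals; anything between is truncated at two decimals.  Full
    precision is kept internally — this is display only.
    """
    if fold >= 10:
        return str(round(fold))
    if fold < 1:
        return f"{fold:.3f}"
    return f"{math.floor(fold * 100) / 100:.2f}"


def segment_shares(abundance: AbundanceTable, meta: VirusMeta) -> SegmentShareTable:
    """Normalized segment abundances for one multipartite virus.

    Libraries where the virus is not detected (whole-genome total zero) are
    omitted rather than reported as NaN.
    """
    shares: dict[tuple[str, str], float] = {}
    libs_present: list[str] = []
    for lib in abundance.library_ids:
        seg_vals = {s: abundance.value(s, lib) for s in meta.segment_ids}
        total = sum(seg_vals.values())
        if total <= 0 or not any(
            abundance.is_detected(s, lib) for s in meta.segment_ids
        ):
            continue
        libs_present.append(lib)
        for s, v in seg_vals.items():
            shares[(s, lib)] = v / total
    return SegmentShareTable(
        shares=shares, segment_ids=list(meta.segment_ids), library_ids=libs_present
    )
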