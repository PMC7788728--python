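"""Host-association inference: the four-criterion classifier and the
model/results interface tying the pipeline together.

A candidate virus found in host transcriptomes may be a genuine resident or
dietary/environmental carry-over.  Four criteria separate the two:

i.   abundance within the range of (or above) the host's housekeeping genes,
     judged by a rank-based post hoc against each gene;
ii.  whole-virus abundance above a detection threshold (default 0.01% of
     library reads, strict);
iii. phylogenetic proximity to another insect virus (metadata flag);
iv.  complete coding regions recovered (metadata flag).

The default call rule makes criterion iv mandatory and then requires at
least two of the remaining three.  A literal "at least k of 4" rule is also
available: the two differ for low-abundance partial genomes that sit below
every housekeeping gene yet satisfy two metadata-ish criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, compute_abundance, segment_shares
from .io import Config, CountTable, ValidationError, VirusMeta, validate_virus_set
from .stats import GroupComparison, GroupSample, rank_lsd_posthoc

__all__ = [
    "CriterionProfile",
    "HostCall",
    "criterion_abundance_range",
    "criterion_threshold",
    "classify",
    "build_group_samples",
    "HostAssociationModel",
    "HostAssociationResults",
]

HOUSEKEEPING_GENES = ("cox1", "rpl18", "eif1-beta")


@dataclass
class CriterionProfile:
    """Per-virus evaluation of the four criteria, with evidence."""

    virus_id: str
    c1_within_housekeeping_range: bool
    c2_above_threshold: bool
    c3_insect_phylogeny: bool
    c4_complete_cds: bool
    c1_letters: dict[str, str] = field(default_factory=dict)
    c2_median_abundance: float = float("nan")
    c2_threshold: float = float("nan")

    @property
    def criteria(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.c1_within_housekeeping_range,
            self.c2_above_threshold,
            self.c3_insect_phylogeny,
            self.c4_complete_cds,
        )

    @property
    def n_met(self) -> int:
        return sum(self.criteria)


@dataclass(frozen=True)
class HostCall:
    virus_id: str
    hosted: bool
    n_criteria_met: int
    rule_used: str


def criterion_abundance_range(comparison: GroupComparison, virus_id: str,
                              genes: Sequence[str] = HOUSEKEEPING_GENES) -> bool:
    """Criterion i: abundance within or above the housekeeping range.

    True unless the virus is significantly *below* every housekeeping gene:
    sharing a letter with any gene, or exceeding any gene's mean rank,
    qualifies.
    """
    below_all = all(
        comparison.significant(virus_id, g)
        and comparison.mean_ranks[virus_id] < comparison.mean_ranks[g]
        for g in genes
    )
    return not below_all


def criterion_threshold(
    abundance: AbundanceTable,
    virus: VirusMeta,
    threshold: float = 0.01,
    aggregation: str = "median",
) -> tuple[bool, float]:
    """Criterion ii: whole-virus abundance above ``threshold`` percent.

    The comparison is strict (exactly the threshold fails).  Per-library
    values over the virus's detected libraries are aggregated by ``median``
    (default) or ``any`` (one qualifying library suffices).  Returns the
    decision and the aggregated abundance used as evidence.
    """
    vals = abundance.detected_values(virus.virus_id)
    if not vals:
        import warnings

        warnings.warn(f"virus {virus.virus_id!r} never detected; criterion fails")
        return False, float("nan")
    if aggregation == "median":
        agg = median(vals)
        return agg > threshold, agg
    if aggregation == "any":
        agg = max(vals)
        return agg > threshold, agg
    raise ValidationError(f"unknown aggregation {aggregation!r}")


def classify(profile: CriterionProfile, rule: str = "cds_plus_2", k: int = 2) -> HostCall:
    """Turn a criterion profile into a hosted/not-hosted call.

    ``cds_plus_2``: hosted iff complete CDS (iv) and at least two of the
    other three criteria.  ``at_least_k``: hosted iff at least ``k`` of the
    four criteria, with no criterion privileged.
    """
    c1, c2, c3, c4 = profile.criteria
    if rule == "cds_plus_2":
        hosted = c4 and (c1 + c2 + c3) >= 2
    elif rule == "at_least_k":
        hosted = profile.n_met >= k
    else:
        raise ValidationError(f"unknown rule {rule!r}")
    return HostCall(
        virus_id=profile.virus_id,
        hosted=hosted,
        n_criteria_met=profile.n_met,
        rule_used=rule if rule != "at_least_k" else f"at_least_{k}",
    )


def build_group_samples(
    abundance: AbundanceTable,
    virus: VirusMeta,
    genes: Sequence[str] = HOUSEKEEPING_GENES,
    log_transform: bool = True,
) -> list[GroupSample]:
    """Groups for the virus-vs-housekeeping comparison.

    Detection gating: only libraries where the virus is detected enter, and
    the housekeeping groups are restricted to those same libraries so every
    group is sampled from identical conditions.  The optional log transform
    is a no-op for the rank statistics downstream but is applied where
    configured for parity with common practice.
    """
    libs = abundance.detected_libraries(virus.virus_id)
    if not libs:
        raise ValidationError(f"virus {virus.virus_id!r} detected in no library")

    def tf(x: float) -> float:
        return math.log(x) if log_transform else x

    groups = [
        GroupSample(virus.virus_id, tuple(tf(abundance.value(virus.virus_id, l)) for l in libs))
    ]
    for g in genes:
        groups.append(GroupSample(g, tuple(tf(abundance.value(g, l)) for l in libs)))
    return groups


class HostAssociationModel:
    """Host-association inference over a count (or abundance) table.

    Parameters
    ----------
    counts
        A :class:`~virhost.io.CountTable`; abundances are derived from it.
        Alternatively use :meth:`from_abundance` when only a percentage
        matrix is available (e.g. a published abundance table).
    viruses
        Virus metadata: segment membership plus the two boolean criteria
        that come from upstream analyses (insect-virus phylogeny, complete
        CDS).
    config
        Thresholds, significance level and call rule; defaults follow the
        study conditions (0.01% threshold, alpha 0.05, CDS-mandatory rule).

    Examples
    --------
    >>> from virhost import presets
    >>> model = HostAssociationModel(presets.table2_counts(), presets.table2_viruses())
    >>> res = model.fit()
    >>> sorted(c.virus_id for c in res.calls if c.hosted)
    ['SINV-14', 'SINV-15', 'SINV-16', 'SINV-17']
    """

    def __init__(
        self,
        counts: CountTable | None,
        viruses: Sequence[VirusMeta],
        config: Config | None = None,
        abundance: AbundanceTable | None = None,
        genes: Sequence[str] = HOUSEKEEPING_GENES,
    ) -> None:
        if counts is None and abundance is None:
            raise ValidationError("provide counts or a precomputed abundance table")
        validate_virus_set(viruses)
        self.counts = counts
        self.viruses = list(viruses)
        self.config = config or Config()
        self.genes = tuple(genes)
        self._abundance = abundance

    @classmethod
    def from_abundance(
        cls,
        abundance: AbundanceTable,
        viruses: Sequence[VirusMeta],
        config: Config | None = None,
        genes: Sequence[str] = HOUSEKEEPING_GENES,
    ) -> "HostAssociationModel":
        """Build directly from an abundance percentage table (counts unknown)."""
        return cls(None, viruses, config=config, abundance=abundance, genes=genes)

    def fit(self) -> "HostAssociationResults":
        cfg = self.config
        if self._abundance is not None:
            ab = self._ensure_totals(self._abundance)
        else:
            ab = compute_abundance(self.counts, self.viruses)
        comparisons: dict[str, GroupComparison] = {}
        profiles: dict[str, CriterionProfile] = {}
        calls: list[HostCall] = []
        for v in self.viruses:
            if not ab.detected_libraries(v.virus_id):
                profile = CriterionProfile(
                    virus_id=v.virus_id,
                    c1_within_housekeeping_range=False,
                    c2_above_threshold=False,
                    c3_insect_phylogeny=v.insect_phylo,
                    c4_complete_cds=v.complete_cds,
                    c2_threshold=cfg.abundance_threshold_percent,
                )
            else:
                groups = build_group_samples(ab, v, self.genes, cfg.log_transform)
                comp = rank_lsd_posthoc(groups, alpha=cfg.alpha)
                comparisons[v.virus_id] = comp
                c1 = criterion_abundance_range(comp, v.virus_id, self.genes)
                c2, med = criterion_threshold(
                    ab, v, cfg.abundance_threshold_percent, cfg.threshold_aggregation
                )
                profile = CriterionProfile(
                    virus_id=v.virus_id,
                    c1_within_housekeeping_range=c1,
                    c2_above_threshold=c2,
                    c3_insect_phylogeny=v.insect_phylo,
                    c4_complete_cds=v.complete_cds,
                    c1_letters=dict(comp.letters),
                    c2_median_abundance=med,
                    c2_threshold=cfg.abundance_threshold_percent,
                )
            profiles[v.virus_id] = profile
            calls.append(classify(profile, cfg.rule, cfg.k))
        return HostAssociationResults(
            model=self,
            abundance=ab,
            comparisons=comparisons,
            profiles=profiles,
            calls=calls,
        )

    def _ensure_totals(self, ab: AbundanceTable) -> AbundanceTable:
        """Add whole-virus rows to a percentage-mode table when missing."""
        values = dict(ab.values)
        detected = dict(ab.detected)
        order = list(ab.feature_ids)
        for v in self.viruses:
            if v.virus_id in ab.feature_ids:
                continue
            for lib in ab.library_ids:
                present = [s for s in v.segment_ids if detected.get((s, lib), False)]
                if present:
                    values[(v.virus_id, lib)] = sum(values[(s, lib)] for s in present)
                    detected[(v.virus_id, lib)] = True
                else:
                    detected[(v.virus_id, lib)] = False
            order.append(v.virus_id)
        return AbundanceTable(
            values=values, detected=detected, feature_ids=order, library_ids=list(ab.library_ids)
        )


class HostAssociationResults:
    """Fitted host-association pipeline: abundances, comparisons, calls."""

    def __init__(
        self,
        model: HostAssociationModel,
        abundance: AbundanceTable,
        comparisons: Mapping[str, GroupComparison],
        profiles: Mapping[str, CriterionProfile],
        calls: Sequence[HostCall],
    ) -> None:
        self.model = model
        self.abundance = abundance
        self.comparisons = dict(comparisons)
        self.profiles = dict(profiles)
        self.calls = list(calls)

    @property
    def hosted(self) -> list[str]:
        return [c.virus_id for c in self.calls if c.hosted]

    def call(self, virus_id: str) -> HostCall:
        for c in self.calls:
            if c.virus_id == virus_id:
                return c
        raise KeyError(virus_id)

    def segment_shares(self, virus_id: str):
        meta = next(v for v in self.model.viruses if v.virus_id == virus_id)
        return segment_shares(self.abundance, meta)

    def fold_vs_gene(self, virus_id: str, gene: str, library_id: str) -> float:
        from .abundance import fold_vs_gene

        return fold_vs_gene(
            self.abundance.value(virus_id, library_id),
            self.abundance.value(gene, library_id),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            p = self.profiles[c.virus_id]
            rows.append(
                {
                    "virus_id": c.virus_id,
                    "c1_range": p.c1_within_housekeeping_range,
                    "c2_threshold": p.c2_above_threshold,
                    "c3_insect_phylo": p.c3_insect_phylogeny,
                    "c4_complete_cds": p.c4_complete_cds,
                    "n_met": c.n_criteria_met,
                    "hosted": c.hosted,
                    "rule": c.rule_used,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Host-association inference",
            "=" * 60,
            f"libraries: {len(self.abundance.library_ids)}   "
            f"viruses: {len(self.model.viruses)}   "
            f"alpha: {cfg.alpha}   threshold: {cfg.abundance_threshold_percent}%   "
            f"rule: {cfg.rule}",
            "",
            f"{'virus':<10} {'c1':>3} {'c2':>3} {'c3':>3} {'c4':>3} {'met':>4} "
            f"{'hosted':>7}  letters",
            "-" * 60,
        ]
        for c in self.calls:
            p = self.profiles[c.virus_id]
            letters = p.c1_letters.get(c.virus_id, "-")
            lines.append(
                f"{c.virus_id:<10} "
                f"{int(p.c1_within_housekeeping_range):>3} "
                f"{int(p.c2_above_threshold):>3} "
                f"{int(p.c3_insect_phylogeny):>3} "
                f"{int(p.c4_complete_cds):>3} "
                f"{c.n_criteria_met:>4} "
                f"{str(c.hosted):>7}  {letters}"
            )
        lines.append("-" * 60)
        lines.append(f"hosted: {', '.join(self.hosted) or 'none'}")
        return "\n".join(lines)
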