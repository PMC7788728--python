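"""Rank-based group comparison: Kruskal-Wallis and rank-LSD post hoc.

The k-sample comparison is the tie-corrected Kruskal-Wallis H on midranks,
with the p-value from the chi-square approximation on k-1 degrees of
freedom.  The post hoc is the Conover rank-LSD procedure: group mean ranks
are compared against a least significant difference built from the pooled
rank variance, deflated by (N-1-H)/(N-k), with a Student-t quantile on N-k
degrees of freedom and no multiplicity adjustment (Fisher's unprotected
LSD).  Pairwise outcomes are summarised as a compact letter display: two
groups share a letter iff their difference is not significant.

Because everything here is computed on ranks, any strictly monotone
transform of the data (e.g. a log transform applied before testing) leaves
H, the p-value and the post-hoc outcome unchanged.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .abundance import AbundanceTable
from .io import ValidationError

__all__ = [
    "GroupSample",
    "PairwiseResult",
    "GroupComparison",
    "kruskal_wallis",
    "rank_lsd_posthoc",
    "compact_letter_display",
    "housekeeping_spread",
]


@dataclass(frozen=True)
class GroupSample:
    """One group's observations (e.g. a virus's abundances across libraries)."""

    group_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValidationError(f"group {self.group_id!r} has no values")


@dataclass(frozen=True)
class PairwiseResult:
    mean_rank_diff: float
    lsd: float
    significant: bool


@dataclass
class GroupComparison:
    """Kruskal-Wallis outcome plus the full pairwise rank-LSD table."""

    H: float
    p_value: float
    mean_ranks: dict[str, float]
    n: dict[str, int]
    pairwise: dict[tuple[str, str], PairwiseResult]
    letters: dict[str, str]
    alpha: float

    def significant(self, a: str, b: str) -> bool:
        if a == b:
            return False
        key = (a, b) if (a, b) in self.pairwise else (b, a)
        return self.pairwise[key].significant

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "group": g,
                "n": self.n[g],
                "mean_rank": self.mean_ranks[g],
                "letter": self.letters[g],
            }
            for g in self.mean_ranks
        ]
        return pd.DataFrame(rows)


def _pooled_midranks(groups: Sequence[GroupSample]) -> tuple[np.ndarray, list[np.ndarray]]:
    values = np.concatenate([np.asarray(g.values, dtype=float) for g in groups])
    ranks = sps.rankdata(values)
    sizes = np.cumsum([len(g.values) for g in groups])[:-1]
    return ranks, np.split(ranks, sizes)


def kruskal_wallis(groups: Sequence[GroupSample]) -> dict[str, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    With every observation identical the statistic is defined as 0 and the
    p-value as 1 (no evidence of any difference), rather than an error.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    ranks, per_group = _pooled_midranks(groups)
    N = len(ranks)
    k = len(groups)
    values = np.concatenate([np.asarray(g.values, dtype=float) for g in groups])
    if np.all(values == values[0]):
        return {"H": 0.0, "p_value": 1.0}
    H = 12.0 / (N * (N + 1)) * sum(
        len(r) * r.mean() ** 2 for r in per_group
    ) - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    H /= correction
    p = float(sps.chi2.sf(H, k - 1))
    return {"H": float(H), "p_value": p}


def rank_lsd_posthoc(groups: Sequence[GroupSample], alpha: float = 0.05) -> GroupComparison:
    """Pairwise mean-rank comparisons with the Conover least significant
    difference, plus a compact letter display.

    Groups i and j differ at level ``alpha`` iff

        |Rbar_i - Rbar_j| > t(1 - alpha/2, N - k)
                            * sqrt(S^2 * (N - 1 - H) / (N - k)
                                   * (1/n_i + 1/n_j))

    where S^2 is the variance of all N pooled midranks and H the
    tie-corrected Kruskal-Wallis statistic.
    """
    kw = kruskal_wallis(groups)
    H = kw["H"]
    ranks, per_group = _pooled_midranks(groups)
    N, k = len(ranks), len(groups)
    if N - k <= 0:
        raise ValidationError(
            f"insufficient replication: N={N} observations for k={k} groups"
        )
    names = [g.group_id for g in groups]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate group ids")
    mean_ranks = {g.group_id: float(r.mean()) for g, r in zip(groups, per_group)}
    sizes = {g.group_id: len(g.values) for g in groups}
    S2 = float((np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0) / (N - 1))
    tq = float(sps.t.ppf(1 - alpha / 2, N - k))
    deflate = (N - 1 - H) / (N - k)
    # H can exceed N-1 only through the tie correction; clamp at 0 so the
    # LSD stays real (all pairs then significant whenever ranks differ).
    deflate = max(deflate, 0.0)
    pairwise: dict[tuple[str, str], PairwiseResult] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = abs(mean_ranks[a] - mean_ranks[b])
            lsd = tq * np.sqrt(S2 * deflate * (1.0 / sizes[a] + 1.0 / sizes[b]))
            pairwise[(a, b)] = PairwiseResult(
                mean_rank_diff=float(diff),
                lsd=float(lsd),
                significant=bool(diff > lsd),
            )
    letters = compact_letter_display(mean_ranks, pairwise)
    return GroupComparison(
        H=H,
        p_value=kw["p_value"],
        mean_ranks=mean_ranks,
        n=sizes,
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
    )


def compact_letter_display(
    mean_ranks: Mapping[str, float],
    pairwise: Mapping[tuple[str, str], PairwiseResult],
) -> dict[str, str]:
    """Assign letters so groups share a letter iff not significantly different.

    Letters label the maximal cliques of the non-significance graph, ordered
    so that 'a' goes to the clique containing the highest mean rank.  Each
    group's string concatenates the letters of every clique it belongs to.
    """
    graph = nx.Graph()
    graph.add_nodes_from(mean_ranks)
    for (a, b), res in pairwise.items():
        if not res.significant:
            graph.add_edge(a, b)
    cliques = [tuple(sorted(c, key=lambda g: -mean_ranks[g])) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: (-max(mean_ranks[g] for g in c), c))
    letters: dict[str, list[str]] = {g: [] for g in mean_ranks}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for g in clique:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def housekeeping_spread(
    abundance: AbundanceTable, genes: Sequence[str] = ("cox1", "rpl18", "eif1-beta")
) -> list[str]:
    """Reference genes ordered by median abundance (descending) across the
    libraries where each is detected."""
    meds = {}
    for g in genes:
        vals = abundance.detected_values(g)
        if not vals:
            raise ValidationError(f"gene {g!r} not detected in any library")
        meds[g] = median(vals)
    return sorted(genes, key=lambda g: -meds[g])
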