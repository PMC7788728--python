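"""Compositional bias: codon-usage counts, dinucleotide odds ratios, PCA.

Synonymous codon usage and dinucleotide composition carry a host signature:
viruses replicating in different hosts drift toward different codon and
dinucleotide preferences even when their proteins stay conserved.  Counting
codons (raw 64-dimensional counts) and dinucleotide odds ratios
rho(XY) = f(XY) / (f(X) f(Y)) per sequence, then projecting with PCA, lets
groups of sequences with different compositional regimes separate in the
first components.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ValidationError

__all__ = [
    "CODONS",
    "DINUCLEOTIDES",
    "CodonUsageVector",
    "DinucleotideBiasVector",
    "PcaResult",
    "codon_counts",
    "dinucleotide_bias",
    "composition_matrix",
    "pca",
    "group_separation",
    "plot_scores",
]

BASES = "ACGT"
CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
DINUCLEOTIDES: tuple[str, ...] = tuple("".join(d) for d in itertools.product(BASES, repeat=2))


def _normalize(seq: str) -> str:
    """Uppercase, RNA U mapped to T."""
    return seq.upper().replace("U", "T")


@dataclass
class CodonUsageVector:
    sequence_id: str
    counts: dict[str, int]
    group_label: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CODONS], dtype=float)


@dataclass
class DinucleotideBiasVector:
    sequence_id: str
    rho: dict[str, float]
    group_label: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.rho[d] for d in DINUCLEOTIDES], dtype=float)


@dataclass
class PcaResult:
    """Scores, per-component variance fractions and loadings.

    Component signs are fixed by forcing each component's largest-magnitude
    loading positive, so results are bit-reproducible across runs.
    """

    scores: np.ndarray          # (n_sequences, n_components)
    variance_fraction: np.ndarray
    loadings: np.ndarray        # (n_components, n_features)
    mean: np.ndarray
    sequence_ids: list[str]
    feature_names: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sequence_ids, columns=cols)


def codon_counts(
    cds: str, sequence_id: str = "", group_label: str = "", strict: bool = True
) -> CodonUsageVector:
    """Count non-overlapping codons read in frame from the first base.

    In strict mode a length that is not a multiple of 3 is an error; in
    lenient mode trailing bases are dropped with a warning.  Codons
    containing ambiguity codes are skipped with a warning.
    """
    seq = _normalize(cds)
    if len(seq) % 3 != 0:
        if strict:
            raise ValidationError(
                f"CDS length {len(seq)} is not a multiple of 3 (strict mode)"
            )
        warnings.warn(
            f"{sequence_id or 'sequence'}: dropping {len(seq) % 3} trailing base(s)"
        )
        seq = seq[: len(seq) - len(seq) % 3]
    counts = dict.fromkeys(CODONS, 0)
    skipped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in counts:
            counts[codon] += 1
        else:
            skipped += 1
    if skipped:
        warnings.warn(
            f"{sequence_id or 'sequence'}: skipped {skipped} codon(s) with "
            "ambiguity codes"
        )
    return CodonUsageVector(sequence_id=sequence_id, counts=counts, group_label=group_label)


def dinucleotide_bias(
    seq: str, sequence_id: str = "", group_label: str = ""
) -> DinucleotideBiasVector:
    """Odds ratio rho(XY) = f(XY) / (f(X) f(Y)) over the linear sequence.

    Dinucleotides are the L-1 overlapping windows (no wrap-around);
    mononucleotide frequencies come from the full sequence.  Ambiguity codes
    are removed before counting.  rho(XY) is 0 exactly when XY never occurs,
    and 0 by convention when f(X) or f(Y) is 0.
    """
    s = "".join(b for b in _normalize(seq) if b in BASES)
    if len(s) < 2:
        raise ValidationError("need at least 2 unambiguous bases")
    L = len(s)
    mono = {b: s.count(b) / L for b in BASES}
    di_counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(L - 1):
        di_counts[s[i : i + 2]] += 1
    rho = {}
    for d in DINUCLEOTIDES:
        fxy = di_counts[d] / (L - 1)
        denom = mono[d[0]] * mono[d[1]]
        rho[d] = fxy / denom if denom > 0 else 0.0
    return DinucleotideBiasVector(sequence_id=sequence_id, rho=rho, group_label=group_label)


def composition_matrix(
    vectors: Sequence[CodonUsageVector | DinucleotideBiasVector],
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack per-sequence vectors into (matrix, sequence_ids, feature_names)."""
    if not vectors:
        raise ValidationError("no vectors")
    names = CODONS if isinstance(vectors[0], CodonUsageVector) else DINUCLEOTIDES
    mat = np.vstack([v.as_array() for v in vectors])
    return mat, [v.sequence_id for v in vectors], list(names)


def pca(
    matrix: np.ndarray,
    sequence_ids: Sequence[str] | None = None,
    feature_names: Sequence[str] | None = None,
    scale: bool = False,
) -> PcaResult:
    """Principal components of a sequences x features matrix.

    Columns are centered; unit-variance scaling is off by default (raw
    counts keep their natural weighting).  Components come from the singular
    value decomposition and carry variance fractions that sum to 1 over all
    components.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >=2 rows and >=2 columns")
    if np.allclose(X, X[0]):
        raise ValidationError("constant matrix: total variance is zero")
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    model = PCA(n_components=min(X.shape), svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    # sign convention: largest-magnitude loading of each component positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return PcaResult(
        scores=scores,
        variance_fraction=model.explained_variance_ratio_.copy(),
        loadings=loadings,
        mean=model.mean_.copy(),
        sequence_ids=list(sequence_ids or [str(i) for i in range(X.shape[0])]),
        feature_names=list(feature_names or [str(j) for j in range(X.shape[1])]),
    )


def group_separation(
    result: PcaResult, labels: Sequence[str], n_components: int = 2
) -> dict[str, object]:
    """Centroid distances and dispersions of labelled groups on the first
    components.

    Returns ``centroids`` (label -> coordinates), ``dispersion`` (label ->
    RMS distance of members to their centroid; 0 for singletons) and
    ``pairwise_distance`` ((label_i, label_j) -> Euclidean centroid
    distance).
    """
    labels = list(labels)
    if len(labels) != result.scores.shape[0]:
        raise ValidationError("one label per sequence required")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("need at least two groups")
    pts = result.scores[:, :n_components]
    centroids = {}
    dispersion = {}
    for g in uniq:
        sub = pts[[i for i, l in enumerate(labels) if l == g]]
        c = sub.mean(axis=0)
        centroids[g] = c
        dispersion[g] = float(np.sqrt(((sub - c) ** 2).sum(axis=1).mean())) if len(sub) > 1 else 0.0
    pairwise = {
        (a, b): float(np.linalg.norm(centroids[a] - centroids[b]))
        for i, a in enumerate(uniq)
        for b in uniq[i + 1 :]
    }
    return {"centroids": centroids, "dispersion": dispersion, "pairwise_distance": pairwise}


def plot_scores(result: PcaResult, labels: Sequence[str], path: str) -> None:
    """Scatter of the first two components, coloured by group label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = list(labels)
    for g in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == g]
        ax.scatter(result.scores[idx, 0], result.scores[idx, 1], label=g, alpha=0.8)
    vf = result.variance_fraction
    ax.set_xlabel(f"PC1 ({vf[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({vf[1] * 100:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
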