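"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: midranks are found
by explicit counting, the H statistic follows the textbook closed form, and
pairwise decisions re-derive the least significant difference from first
principles with naive loops.
"""

import math

from scipy.stats import chi2, t as tdist


def brute_midranks(values):
    """Midrank of each value by counting smaller/equal elements."""
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def brute_kruskal(groups):
    """Tie-corrected H via the closed-form rank formula.

    groups: list of lists of floats.  Returns (H, p).
    """
    pooled = [v for g in groups for v in g]
    N = len(pooled)
    ranks = brute_midranks(pooled)
    H = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        i += len(g)
        H += (sum(r) ** 2) / len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    # tie correction over distinct values
    correction = 1.0
    if N > 1:
        tie_sum = 0
        for v in set(pooled):
            c = pooled.count(v)
            tie_sum += c**3 - c
        correction = 1.0 - tie_sum / (N**3 - N)
    if correction == 0:
        return 0.0, 1.0
    H /= correction
    return H, float(chi2.sf(H, len(groups) - 1))


def brute_rank_lsd(groups, alpha=0.05):
    """Pairwise significance by the rank-LSD rule, naive implementation.

    Returns dict {(i, j): bool} over group indices i < j.
    """
    pooled = [v for g in groups for v in g]
    N, k = len(pooled), len(groups)
    ranks = brute_midranks(pooled)
    H, _ = brute_kruskal(groups)
    mean_ranks = []
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        i += len(g)
        mean_ranks.append(sum(r) / len(r))
    mean_all = sum(ranks) / N
    S2 = sum((r - mean_all) ** 2 for r in ranks) / (N - 1)
    tq = float(tdist.ppf(1 - alpha / 2, N - k))
    deflate = max((N - 1 - H) / (N - k), 0.0)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            lsd = tq * math.sqrt(S2 * deflate * (1 / len(groups[i]) + 1 / len(groups[j])))
            out[(i, j)] = abs(mean_ranks[i] - mean_ranks[j]) > lsd
    return out


def brute_codon_counts(seq):
    """Triplet counter via an explicit sliding index."""
    seq = seq.upper().replace("U", "T")
    counts = {}
    i = 0
    while i + 3 <= len(seq):
        codon = seq[i] + seq[i + 1] + seq[i + 2]
        if all(b in "ACGT" for b in codon):
            counts[codon] = counts.get(codon, 0) + 1
        i += 3
    return counts


def brute_terminal_match(sequence, motif, end, max_mismatch):
    """Position-by-position terminal comparison; returns mismatch offsets
    (1-based) or None when the distance exceeds the budget."""
    seq = sequence.upper().replace("U", "T")
    m = motif.upper().replace("U", "T")
    window = seq[: len(m)] if end == "five_prime" else seq[len(seq) - len(m):]
    mism = [i + 1 for i in range(len(m)) if window[i] != m[i]]
    return tuple(mism) if len(mism) <= max_mismatch else None
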