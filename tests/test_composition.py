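import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from _oracles import brute_codon_counts
from virhost import presets
from virhost.composition import (
    CODONS,
    DINUCLEOTIDES,
    codon_counts,
    composition_matrix,
    dinucleotide_bias,
    group_separation,
    pca,
)
from virhost.io import ValidationError
from virhost.simulate import CompositionSpec, GroupSpec, gen_cds_set


class TestCodonCounts:
    def test_direct_reading_frame(self):
        v = codon_counts("ATGAAATAA")
        assert v.counts["ATG"] == 1 and v.counts["AAA"] == 1 and v.counts["TAA"] == 1
        assert v.total == 3

    def test_repeated_codon(self):
        assert codon_counts("ATGATGATG").counts["ATG"] == 3

    def test_rna_input_normalized(self):
        assert codon_counts("AUGAAA").counts["ATG"] == 1

    def test_strict_mode_rejects_partial_codon(self):
        with pytest.raises(ValidationError):
            codon_counts("ATGA")

    def test_lenient_mode_drops_tail_with_warning(self):
        with pytest.warns(UserWarning):
            v = codon_counts("ATGA", strict=False)
        assert v.total == 1

    def test_ambiguity_codon_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            v = codon_counts("ATGNNNAAA")
        assert v.total == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sliding_index_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        ours = codon_counts(seq).counts
        expected = brute_codon_counts(seq)
        for c in CODONS:
            assert ours[c] == expected.get(c, 0)

    def test_counts_conserve_length(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=999))
        assert codon_counts(seq).total * 3 == 999


class TestDinucleotideBias:
    def test_homopolymer(self):
        rho = dinucleotide_bias("A" * 50).rho
        assert rho["AA"] == pytest.approx(1.0)
        assert all(rho[d] == 0.0 for d in DINUCLEOTIDES if d != "AA")

    def test_acgt_hand_computation(self):
        # f(AC)=f(CG)=f(GT)=1/3; each base frequency 1/4 -> rho = 16/3
        rho = dinucleotide_bias("ACGT").rho
        for d in ("AC", "CG", "GT"):
            assert rho[d] == pytest.approx(16 / 3)
        assert rho["AA"] == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            dinucleotide_bias("A")

    def test_iid_uniform_sequence_has_unit_odds_ratios(self):
        """On an iid uniform sequence of length 1e5 every odds ratio is 1
        within 0.05 (law of large numbers)."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        rho = dinucleotide_bias(seq).rho
        for d in DINUCLEOTIDES:
            assert rho[d] == pytest.approx(1.0, abs=0.05)

    def test_reversal_changes_rho_when_composition_is_asymmetric(self):
        # AAC: forward has AA and AC; reversed (CAA) has CA and AA
        fwd = dinucleotide_bias("AACAACAAC").rho
        rev = dinucleotide_bias("AACAACAAC"[::-1]).rho
        assert fwd != rev
        # but a reversal-symmetric sequence is invariant
        pal = "ACGTTGCA"
        assert dinucleotide_bias(pal).rho == dinucleotide_bias(pal[::-1]).rho


class TestPca:
    def test_single_varying_feature_captures_all_variance(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        res = pca(X)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            pca(np.ones((4, 3)))

    @pytest.mark.parametrize("seed", range(10))
    def test_variance_fractions_match_covariance_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 5))
        res = pca(X)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.allclose(res.variance_fraction, eig / eig.sum(), atol=1e-10)
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        res = pca(X)
        assert np.allclose(res.scores @ res.loadings, X - res.mean, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        a, b = pca(X), pca(X.copy())
        assert np.array_equal(a.scores, b.scores)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_planted_groups_separate_on_pc1(self):
        """Two groups generated with disjoint codon preferences put their
        centroids further apart on PC1 than 3x the within-group spread."""
        spec = CompositionSpec(
            groups=[
                GroupSpec("a", 10, 900, {**{c: 0.02 for c in CODONS}, "GCA": 4.0, "CCA": 4.0}),
                GroupSpec("b", 10, 900, {**{c: 0.02 for c in CODONS}, "GCG": 4.0, "CCG": 4.0}),
            ],
            seed=11,
        )
        records, labels = gen_cds_set(spec)
        mat, ids, feats = composition_matrix(
            [codon_counts(str(r.seq), r.id) for r in records]
        )
        res = pca(mat, ids, feats)
        pc1 = res.scores[:, 0]
        ga = pc1[: 10]
        gb = pc1[10:]
        spread = max(ga.std(ddof=1), gb.std(ddof=1))
        assert abs(ga.mean() - gb.mean()) > 3 * spread


class TestGroupSeparation:
    def test_coincident_groups_distance_zero(self):
        X = np.vstack([np.eye(3)] * 2 + [np.eye(3) * 2])
        res = pca(X)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        sep = group_separation(res, labels)
        assert sep["pairwise_distance"][("a", "b")] == pytest.approx(0.0, abs=1e-10)

    def test_planted_offset_ordering_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 4), scale=0.1)
        X = np.vstack([base, base + [5, 0, 0, 0], base + [20, 0, 0, 0]])
        labels = ["near"] * 8 + ["mid"] * 8 + ["far"] * 8
        sep = group_separation(pca(X), labels)
        d = sep["pairwise_distance"]
        assert d[("far", "near")] > d[("mid", "near")] > 0

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 3))
        res = pca(X)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        swapped = ["b" if l == "a" else "a" if l == "b" else l for l in labels]
        d1 = group_separation(res, labels)["pairwise_distance"]
        d2 = group_separation(res, swapped)["pairwise_distance"]
        assert d1[("a", "c")] == pytest.approx(d2[("b", "c")])
        assert d1[("a", "b")] == pytest.approx(d2[("a", "b")])

    def test_singleton_group_dispersion_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 3))
        sep = group_separation(pca(X), ["a", "a", "a", "a", "solo"])
        assert sep["dispersion"]["solo"] == 0.0


class TestSyntheticRegimes:
    def test_three_group_preset_is_silhouette_separable(self):
        records, labels = gen_cds_set(presets.fig5_spec(seed=1))
        mat, ids, feats = composition_matrix(
            [codon_counts(str(r.seq), r.id) for r in records]
        )
        res = pca(mat, ids, feats)
        score = silhouette_score(res.scores[:, :2], list(labels["group_label"]))
        assert score > 0.5

    def test_dinucleotide_metric_also_separates(self):
        records, labels = gen_cds_set(presets.fig5_spec(seed=2))
        mat, ids, feats = composition_matrix(
            [dinucleotide_bias(str(r.seq), r.id) for r in records]
        )
        res = pca(mat, ids, feats)
        score = silhouette_score(res.scores[:, :2], list(labels["group_label"]))
        assert score > 0.5
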