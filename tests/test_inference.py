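import itertools

import pytest

from virhost import presets
from virhost.inference import (
    CriterionProfile,
    HostAssociationModel,
    classify,
    criterion_abundance_range,
    criterion_threshold,
)
from virhost.io import Config, ValidationError, VirusMeta


def _profile(c1, c2, c3, c4, virus_id="V"):
    return CriterionProfile(
        virus_id=virus_id,
        c1_within_housekeeping_range=c1,
        c2_above_threshold=c2,
        c3_insect_phylogeny=c3,
        c4_complete_cds=c4,
    )


class TestCriterionAbundanceRange:
    def test_lower_than_one_gene_only_passes(self, fitted_counts):
        """The mononegavirus sits below the oxidase gene but level with the
        other two, which keeps it within the housekeeping range."""
        comp = fitted_counts.comparisons["SINV-15"]
        assert comp.significant("SINV-15", "cox1")
        assert comp.share_letter("SINV-15", "rpl18")
        assert comp.share_letter("SINV-15", "eif1-beta")
        assert criterion_abundance_range(comp, "SINV-15")

    def test_above_all_genes_passes(self, fitted_counts):
        comp = fitted_counts.comparisons["SINV-14"]
        assert criterion_abundance_range(comp, "SINV-14")

    def test_below_all_genes_fails(self):
        from virhost.stats import GroupSample, rank_lsd_posthoc

        groups = [
            GroupSample("virus", (0.001, 0.0012, 0.0009, 0.0011, 0.001)),
            GroupSample("cox1", (0.4, 0.45, 0.42, 0.43, 0.41)),
            GroupSample("rpl18", (0.02, 0.025, 0.022, 0.021, 0.024)),
            GroupSample("eif1-beta", (0.08, 0.09, 0.085, 0.088, 0.082)),
        ]
        comp = rank_lsd_posthoc(groups)
        assert not criterion_abundance_range(comp, "virus")


class TestCriterionThreshold:
    def test_densovirus_fails_threshold(self, fitted_counts, table2_viruses):
        v = next(x for x in table2_viruses if x.virus_id == "SINaDNV")
        ok, med = criterion_threshold(fitted_counts.abundance, v, 0.01)
        assert not ok
        assert med == pytest.approx(0.002, abs=1e-3)

    def test_exact_threshold_fails_strict(self):
        from virhost.abundance import AbundanceTable

        ab = AbundanceTable(
            values={("V", "L1"): 0.010}, detected={("V", "L1"): True}
        )
        v = VirusMeta("V", ("V",), True, True)
        ok, _ = criterion_threshold(ab, v, 0.01)
        assert not ok

    def test_mononegavirus_passes_on_median(self, fitted_counts, table2_viruses):
        """Median over the nine positive libraries (0.020%) exceeds the
        0.01% cut."""
        v = next(x for x in table2_viruses if x.virus_id == "SINV-15")
        ok, med = criterion_threshold(fitted_counts.abundance, v, 0.01)
        assert ok
        assert med == pytest.approx(0.020, abs=1e-3)

    def test_duplicating_a_library_row_is_median_stable(self, fitted_counts, table2_viruses):
        from virhost.abundance import AbundanceTable

        v = next(x for x in table2_viruses if x.virus_id == "SINV-15")
        ab = fitted_counts.abundance
        libs = ab.detected_libraries("SINV-15")
        # duplicate the median library; the median of an odd-length sample
        # with its median repeated is unchanged
        vals = sorted(ab.value("SINV-15", l) for l in libs)
        med_val = vals[len(vals) // 2]
        values = {("SINV-15", f"L{i}"): x for i, x in enumerate(vals + [med_val])}
        detected = {k: True for k in values}
        ab2 = AbundanceTable(values=values, detected=detected)
        ok, med = criterion_threshold(ab2, v, 0.01)
        assert ok and med == pytest.approx(med_val)

    def test_never_detected_virus_warns_false(self):
        from virhost.abundance import AbundanceTable

        ab = AbundanceTable(values={}, detected={("V", "L1"): False})
        v = VirusMeta("V", ("V",), True, True)
        with pytest.warns(UserWarning):
            ok, _ = criterion_threshold(ab, v, 0.01)
        assert not ok


class TestClassify:
    def test_incomplete_genome_blocks_default_rule(self):
        call = classify(_profile(True, True, True, False))
        assert not call.hosted

    def test_all_criteria_hosted(self):
        call = classify(_profile(True, True, True, True))
        assert call.hosted and call.n_criteria_met == 4

    def test_all_false_not_hosted_any_rule(self):
        assert not classify(_profile(False, False, False, False)).hosted
        assert not classify(_profile(False, False, False, False), "at_least_k", 2).hosted

    def test_literal_rule_differs_for_partial_genomes(self):
        """Two-of-four without the CDS requirement admits a low-abundance
        partial genome that the default rule rejects."""
        p = _profile(True, False, True, False)
        assert classify(p, "at_least_k", 2).hosted
        assert not classify(p, "cds_plus_2").hosted

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValidationError):
            classify(_profile(True, True, True, True), "bogus")

    @pytest.mark.parametrize("rule,k", [("cds_plus_2", 2), ("at_least_k", 2), ("at_least_k", 3)])
    def test_monotonicity(self, rule, k):
        """Flipping any criterion false->true never turns hosted into
        not-hosted."""
        for bits in itertools.product([False, True], repeat=4):
            base = classify(_profile(*bits), rule, k).hosted
            for i in range(4):
                if not bits[i]:
                    flipped = list(bits)
                    flipped[i] = True
                    assert classify(_profile(*flipped), rule, k).hosted >= base


class TestFullPipeline:
    def test_exactly_four_viruses_hosted(self, fitted_counts):
        assert sorted(fitted_counts.hosted) == [
            "SINV-14", "SINV-15", "SINV-16", "SINV-17",
        ]

    def test_densovirus_is_the_exception(self, fitted_counts):
        call = fitted_counts.call("SINaDNV")
        assert not call.hosted
        profile = fitted_counts.profiles["SINaDNV"]
        assert not profile.c4_complete_cds
        assert not profile.c2_above_threshold

    def test_printed_matrix_path_agrees_with_counts_path(self, fitted_counts, fitted_printed):
        assert sorted(fitted_printed.hosted) == sorted(fitted_counts.hosted)
        for vid, prof in fitted_counts.profiles.items():
            assert fitted_printed.profiles[vid].criteria == prof.criteria

    def test_summary_lists_calls(self, fitted_counts):
        text = fitted_counts.summary()
        assert "SINV-14" in text and "hosted" in text

    def test_results_frame_consistent(self, fitted_counts):
        df = fitted_counts.to_frame()
        assert df.loc[df.virus_id == "SINaDNV", "hosted"].item() == False  # noqa: E712
        assert (df["n_met"] == df[["c1_range", "c2_threshold", "c3_insect_phylo",
                                   "c4_complete_cds"]].sum(axis=1)).all()

    def test_literal_rule_admits_densovirus(self, table2_counts, table2_viruses):
        """Under the unmodified two-of-four rule the partial densovirus is
        called hosted (it is within the housekeeping range on its two
        libraries and clusters with insect viruses) — the reason the
        default rule makes the complete-CDS criterion mandatory."""
        cfg = Config(rule="at_least_k", k=2)
        res = HostAssociationModel(table2_counts, table2_viruses, config=cfg).fit()
        assert "SINaDNV" in res.hosted
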