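"""Unit tests for the propensity table, segments and region statistics."""

import math

import pytest

from batfusion.propensity import (
    STANDARD_AMINO_ACIDS,
    FormerClassThresholds,
    PeptideSegment,
    PropensityLookupError,
    PropensityTable,
    ScaleNotFoundError,
    SequenceError,
    chou_fasman_segment_prediction,
    classify_residue_preferences,
    extract_cterminal_segment,
    load_propensity_table,
    region_mean_propensities,
    score_mutant,
)


class TestPropensityTable:
    def test_bundled_scale_is_complete_and_positive(self, table):
        assert set(STANDARD_AMINO_ACIDS) == {
            r for r in STANDARD_AMINO_ACIDS if table.alpha(r) > 0 and table.beta(r) > 0
        }
        assert "Chou" in table.provenance and "bmrb" in table.provenance.lower()

    def test_glycine_is_a_helix_breaker(self, table):
        assert table.alpha("G") < 1.0

    def test_unknown_scale_id_is_an_error(self):
        with pytest.raises(ScaleNotFoundError):
            load_propensity_table("nonexistent-scale")

    def test_nonstandard_residue_lookup_is_an_error(self, table):
        with pytest.raises(PropensityLookupError):
            table.alpha("X")

    def test_incomplete_table_rejected(self):
        values = {r: (1.0, 1.0, None) for r in STANDARD_AMINO_ACIDS[:-1]}
        with pytest.raises(ValueError, match="20 standard"):
            PropensityTable("broken", values, "test")

    def test_nonpositive_value_rejected(self):
        values = {r: (1.0, 1.0, None) for r in STANDARD_AMINO_ACIDS}
        values["A"] = (0.0, 1.0, None)
        with pytest.raises(ValueError, match="strictly positive"):
            PropensityTable("broken", values, "test")


class TestSegments:
    def test_suffix_extraction(self):
        seg = extract_cterminal_segment("ACDEFG", 3, "toy")
        assert seg.sequence == "EFG"
        assert seg.region_label == "C-terminal 3"

    def test_syb2_anchor_has_a_lone_cysteine(self, syb2):
        assert len(syb2) == 22
        assert len(syb2.cysteine_positions) == 1

    def test_syx1a_anchor_has_tandem_cysteines(self, syx1a):
        assert len(syx1a) == 23
        c1, c2 = syx1a.cysteine_positions
        assert c2 == c1 + 1

    def test_both_anchors_contain_helix_breaking_glycine(self, syb2, syx1a):
        assert syb2.glycine_positions and syx1a.glycine_positions

    def test_overlong_window_rejected(self):
        with pytest.raises(SequenceError):
            extract_cterminal_segment("ACDEFG", 7, "toy")

    @pytest.mark.parametrize("bad", ["", "ACX", "AC1", "AC DE"])
    def test_nonstandard_sequences_rejected(self, bad):
        with pytest.raises(SequenceError):
            PeptideSegment(id="bad", sequence=bad)

    def test_sequences_normalised_on_ingest(self):
        seg = PeptideSegment(id="t", sequence="  acdef ")
        assert seg.sequence == "ACDEF"


class TestRegionMeans:
    def test_homopolymer_means_equal_table_entries(self, table):
        seg = PeptideSegment(id="a4", sequence="AAAA")
        ma, mb = region_mean_propensities(seg, table)
        assert ma == table.alpha("A") and mb == table.beta("A")

    def test_toy_tripeptide_matches_hand_summed_oracle(self, table):
        # independent oracle: explicit lookup-and-average over "GIV"
        expect_a = (table.alpha("G") + table.alpha("I") + table.alpha("V")) / 3
        expect_b = (table.beta("G") + table.beta("I") + table.beta("V")) / 3
        ma, mb = region_mean_propensities(PeptideSegment(id="giv", sequence="GIV"), table)
        assert math.isclose(ma, expect_a, rel_tol=0, abs_tol=1e-15)
        assert math.isclose(mb, expect_b, rel_tol=0, abs_tol=1e-15)
        # frozen values from the bundled 1978 constants
        assert round(ma, 4) == round((0.57 + 1.08 + 1.06) / 3, 4)
        assert round(mb, 4) == round((0.75 + 1.60 + 1.70) / 3, 4)


class TestClassification:
    def test_valine_homopolymer_all_beta(self, table):
        rep = classify_residue_preferences(PeptideSegment(id="v3", sequence="VVV"), table)
        assert (rep.n_beta_preferring, rep.n_helix_preferring, rep.n_tie) == (3, 0, 0)

    def test_counts_partition_the_sequence(self, table, syb2):
        rep = classify_residue_preferences(syb2, table)
        assert rep.n_helix_preferring + rep.n_beta_preferring + rep.n_tie == len(syb2)

    def test_report_means_match_region_means(self, table, syx1a):
        rep = classify_residue_preferences(syx1a, table)
        ma, mb = region_mean_propensities(syx1a, table)
        assert rep.mean_alpha == ma and rep.mean_beta == mb

    def test_former_class_thresholds(self):
        th = FormerClassThresholds()
        assert th.classify(1.36) == "strong former"
        assert th.classify(1.03) == "weak former"
        assert th.classify(0.94) == "indifferent"
        assert th.classify(0.75) == "breaker-leaning"


class TestMutants:
    def test_empty_substitution_list_is_identity(self, table, syb2):
        rep, da, db = score_mutant(syb2, [], table)
        assert da == 0.0 and db == 0.0
        assert "".join(s.residue for s in rep.per_residue) == syb2.sequence

    def test_single_substitution_closed_form(self, table):
        seg = PeptideSegment(id="i8", sequence="IIIIIIII")
        n = len(seg)
        _, da, db = score_mutant(seg, [(3, "L")], table)
        assert math.isclose(da, (table.alpha("L") - table.alpha("I")) / n, abs_tol=1e-12)
        assert math.isclose(db, (table.beta("L") - table.beta("I")) / n, abs_tol=1e-12)

    def test_beta_destabilising_substitutions_lower_mean_beta(self, table):
        # Ile→Leu everywhere: Leu has lower strand propensity than Ile
        seg = PeptideSegment(id="i6", sequence="IIIIII")
        _, da, db = score_mutant(seg, [(i, "L") for i in range(1, 7)], table)
        assert db < 0

    def test_deltas_consistent_with_recomputation(self, table, syb2):
        subs = [(1, "A"), (5, "W")]
        mut_rep, da, db = score_mutant(syb2, subs, table)
        wt_a, wt_b = region_mean_propensities(syb2, table)
        assert math.isclose(da, mut_rep.mean_alpha - wt_a, abs_tol=1e-15)
        assert math.isclose(db, mut_rep.mean_beta - wt_b, abs_tol=1e-15)

    def test_out_of_range_position_rejected(self, table, syb2):
        with pytest.raises(SequenceError):
            score_mutant(syb2, [(99, "A")], table)


class TestStatePrediction:
    @pytest.mark.parametrize(
        "residue,expected",
        [("V", "E"), ("E", "H"), ("G", "C")],
        ids=["strand-former", "helix-former", "breaker"],
    )
    def test_homopolymer_states(self, table, residue, expected):
        seg = PeptideSegment(id=f"{residue}10", sequence=residue * 10)
        assert chou_fasman_segment_prediction(seg, table) == expected * 10

    def test_prediction_covers_every_residue(self, table, syb2):
        states = chou_fasman_segment_prediction(syb2, table)
        assert len(states) == len(syb2)
        assert set(states) <= {"H", "E", "C"}

    def test_short_segment_rejected(self, table):
        with pytest.raises(SequenceError):
            chou_fasman_segment_prediction(PeptideSegment(id="s", sequence="VVVVV"), table)
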