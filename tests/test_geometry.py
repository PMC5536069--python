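"""Unit and property tests for the fusion-geometry operations."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from batfusion import geometry as g

P = g.GeometryParams()


class TestLengths:
    @pytest.mark.parametrize(
        "n,expected", [(23, 8.05), (0, 0.0), (10, 3.5)], ids=["syx", "empty", "decamer"]
    )
    def test_beta_strand_length(self, n, expected):
        assert g.length_beta(n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "n,expected", [(23, 3.45), (0, 0.0), (36, 5.4)], ids=["syx", "empty", "ten-turns"]
    )
    def test_helix_length(self, n, expected):
        assert g.length_alpha(n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "n,expected", [(23, 4.6), (0, 0.0), (22, 4.4)], ids=["syx", "empty", "syb"]
    )
    def test_retraction(self, n, expected):
        assert g.retraction(n) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(g.GeometryError):
            g.length_beta(-1)


class TestPore:
    def test_published_inputs_give_three_nm(self):
        assert g.pore_diameter(4.5) == pytest.approx(3.0)

    def test_pore_closes_when_coat_swallows_retraction(self):
        assert g.pore_diameter(3.0, g.GeometryParams(coat_width=3.0)) == 0.0

    def test_unrounded_inputs(self):
        assert g.pore_diameter(4.6, g.GeometryParams(coat_width=2.5)) == pytest.approx(4.2)

    def test_negative_retraction_rejected(self):
        with pytest.raises(g.GeometryError):
            g.pore_diameter(-0.1)


class TestContactZone:
    def test_end_to_end_span(self):
        assert g.contact_span(22, 23, g.BAT) == pytest.approx(15.75)

    def test_side_by_side_span(self):
        assert g.contact_span(22, 23, g.SHORT_BAT) == pytest.approx(8.05)

    def test_two_single_residues_end_to_end(self):
        assert g.contact_span(1, 1, g.BAT) == pytest.approx(0.70)

    def test_unknown_variant_rejected(self):
        with pytest.raises(g.GeometryError):
            g.contact_span(22, 23, "diagonal")

    @pytest.mark.parametrize(
        "span,expected", [(16.0, 201.06), (0.0, 0.0), (8.0, 50.27)]
    )
    def test_circular_area(self, span, expected):
        assert g.contact_area_circular(span) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize(
        "span,retracted,expected",
        [(8.0, 3.5, 1.0), (7.0, 3.5, 0.0), (8.05, 3.45, 1.15)],
        ids=["published", "full-coverage", "unrounded"],
    )
    def test_central_gap(self, span, retracted, expected):
        assert g.short_bat_central_gap(span, retracted) == pytest.approx(expected)


class TestFullReport:
    def test_fields_equal_single_op_outputs(self):
        results = g.full_report(22, 23)
        for variant, res in results.items():
            assert res.length_beta == g.length_beta(23)
            assert res.length_alpha == g.length_alpha(23)
            assert res.retraction == g.retraction(23)
            assert res.pore_diameter == g.pore_diameter(g.retraction(23))
            assert res.contact_span == g.contact_span(22, 23, variant)
            assert res.contact_area_circular == g.contact_area_circular(res.contact_span)

    def test_short_variant_central_gap(self):
        res = g.full_report(22, 23)[g.SHORT_BAT]
        assert res.central_gap == pytest.approx(1.15)
        assert g.full_report(22, 23)[g.BAT].central_gap is None

    def test_zero_counts_rejected(self):
        with pytest.raises(g.GeometryError):
            g.full_report(0, 0)


class TestParams:
    def test_defaults_shorten_upon_transition(self):
        assert P.beta_rise_per_residue > P.helix_rise_per_residue

    def test_non_shortening_constants_rejected(self):
        with pytest.raises(g.GeometryError):
            g.GeometryParams(beta_rise_per_residue=0.10)

    def test_retraction_invariant_holds_per_record(self):
        res = g.full_report(22, 23)[g.BAT]
        assert res.retraction == pytest.approx(res.length_beta - res.length_alpha)


counts = st.integers(min_value=0, max_value=500)


@settings(max_examples=100, derandomize=True)
@given(counts)
def test_lengths_linear_in_residue_count(n):
    assert math.isclose(g.length_beta(n), n * 0.35, rel_tol=1e-12)
    assert math.isclose(g.length_alpha(n), n * 0.15, rel_tol=1e-12)
    assert math.isclose(g.retraction(n), n * 0.20, rel_tol=1e-9, abs_tol=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    st.floats(0, 20, allow_nan=False),
    st.floats(0, 20, allow_nan=False),
    st.floats(0, 10, allow_nan=False),
)
def test_pore_monotone_in_retraction_and_coat(r1, r2, coat):
    params = g.GeometryParams(coat_width=coat)
    lo, hi = sorted((r1, r2))
    assert g.pore_diameter(lo, params) <= g.pore_diameter(hi, params)
    wider = g.GeometryParams(coat_width=coat + 1.0)
    assert g.pore_diameter(hi, wider) <= g.pore_diameter(hi, params)
    assert g.pore_diameter(hi, params) >= 0.0


@settings(max_examples=100, derandomize=True)
@given(st.floats(0, 100, allow_nan=False), st.floats(0.001, 100, allow_nan=False))
def test_circular_area_strictly_increasing_in_span(span, delta):
    assert g.contact_area_circular(span + delta) > g.contact_area_circular(span)
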