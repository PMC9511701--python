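"""Reference-model expectations, matrix scores and the CSS-style score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synerstack.hill import HillCurve, hill_response
from synerstack.reference_models import (DoseResponseMatrix, css_score,
                                         expected_bliss, expected_hsa,
                                         expected_loewe, expected_matrix,
                                         expected_zip, score_table,
                                         summarize_synergy)

finite = st.floats(-10, 10, allow_nan=False)
unit = st.floats(0, 1, allow_nan=False)


def make_matrix(curve1, curve2, grid1=None, grid2=None):
    """Matrix with noiseless monotherapy series from the true curves and
    placeholder combination responses (overwrite ``.y`` as needed)."""
    mono1 = curve1.m * np.logspace(-1, 1, 5)
    mono2 = curve2.m * np.logspace(-1, 1, 5)
    g1 = mono1 if grid1 is None else np.asarray(grid1, float)
    g2 = mono2[1:4] if grid2 is None else np.asarray(grid2, float)
    D1, D2 = np.meshgrid(g1, g2, indexing="ij")
    m = DoseResponseMatrix(
        "A", "B", "c1", D1.ravel(), D2.ravel(), np.zeros(D1.size),
        (mono1, hill_response(mono1, curve1)),
        (mono2, hill_response(mono2, curve2)))
    return m


class TestPointwiseExpectations:
    @pytest.mark.parametrize("y1,y2,expected", [
        (0.0, 0.6, 0.6), (1.0, 0.3, 1.0), (0.5, 0.5, 0.75)])
    def test_bliss_values(self, y1, y2, expected):
        assert expected_bliss(y1, y2) == pytest.approx(expected)

    @pytest.mark.parametrize("y1,y2,expected", [
        (0.2, 0.7, 0.7), (0.4, 0.4, 0.4), (-0.1, 0.0, 0.0)])
    def test_hsa_values(self, y1, y2, expected):
        assert expected_hsa(y1, y2) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(finite, finite)
    def test_bliss_and_hsa_are_symmetric(self, a, b):
        assert expected_bliss(a, b) == pytest.approx(expected_bliss(b, a))
        assert expected_hsa(a, b) == expected_hsa(b, a)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(unit, unit)
    def test_bliss_dominates_hsa_on_unit_interval(self, a, b):
        assert expected_bliss(a, b) >= expected_hsa(a, b) - 1e-12

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            expected_bliss(np.nan, 0.1)


class TestLoewe:
    def test_midpoint_at_total_dose_m(self):
        curve = HillCurve(0.0, 1.0, 4.0, 2.7)
        assert expected_loewe(1.0, 3.0, curve) == pytest.approx(0.5)

    def test_zero_doses_give_emin(self):
        assert expected_loewe(0.0, 0.0, HillCurve(0.15, 0.9, 1.0, 2.0)) \
            == pytest.approx(0.15)

    def test_printed_form_direct_substitution(self):
        # (0 + 1*(2/1)^2) / (1 + (2/1)^2) = 4/5
        assert expected_loewe(1.0, 1.0, HillCurve(0, 1, 1, 2)) == pytest.approx(0.8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0, 5), st.floats(0, 5), st.floats(0, 5), st.floats(0, 5))
    def test_monotone_in_total_dose(self, a1, a2, b1, b2):
        curve = HillCurve(0.1, 0.9, 1.0, 1.5)
        lo, hi = sorted([(a1 + a2), (b1 + b2)])
        assert expected_loewe(lo, 0.0, curve) <= expected_loewe(hi, 0.0, curve) + 1e-12

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            expected_loewe(-1.0, 0.5, HillCurve(0, 1, 1, 1))


class TestZip:
    def test_both_at_midpoint_gives_three_quarters(self):
        c1, c2 = HillCurve(0, 1, 2.0, 1.3), HillCurve(0, 1, 0.5, 2.1)
        assert expected_zip(2.0, 0.5, c1, c2) == pytest.approx(0.75)

    def test_zero_partner_dose_leaves_single_hill_term(self):
        c1, c2 = HillCurve(0, 1, 1.0, 2.0), HillCurve(0, 1, 3.0, 1.0)
        x = 1.7
        t = (x / c1.m) ** c1.lam
        assert expected_zip(x, 0.0, c1, c2) == pytest.approx(t / (1 + t))

    def test_direct_substitution(self):
        c = HillCurve(0, 1, 1.0, 1.0)
        assert expected_zip(3.0, 1.0, c, c) == pytest.approx(0.875)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_bounded_in_unit_interval(self, x1, x2):
        c1, c2 = HillCurve(0, 1, 1.0, 2.0), HillCurve(0, 1, 5.0, 0.7)
        assert 0.0 <= expected_zip(x1, x2, c1, c2) <= 1.0


class TestSummarize:
    c1 = HillCurve(0.0, 0.9, 1.0, 1.8)
    c2 = HillCurve(0.05, 0.8, 3.0, 1.2)

    @pytest.mark.parametrize("model", ["bliss", "hsa", "loewe", "zip"])
    def test_model_generated_matrix_scores_zero(self, model):
        m = make_matrix(self.c1, self.c2)
        m.y = expected_matrix(m, model)
        assert abs(summarize_synergy(m, model)) < 1e-9

    def test_constant_offset_scales_to_percent(self):
        m = make_matrix(self.c1, self.c2)
        m.y = expected_matrix(m, "bliss") + 0.05
        assert summarize_synergy(m, "bliss") == pytest.approx(5.0)

    def test_hand_averaged_residuals(self):
        m = make_matrix(self.c1, self.c2, grid1=[1.0, 2.0], grid2=[1.0, 3.0])
        m.y = expected_matrix(m, "bliss") + np.array([0.1, -0.1, 0.2, 0.0])
        assert summarize_synergy(m, "bliss") == pytest.approx(5.0)

    def test_no_positive_grid_errors(self):
        m = make_matrix(self.c1, self.c2, grid1=[0.0], grid2=[0.0, 1.0])
        with pytest.raises(ValueError, match="positive"):
            summarize_synergy(m, "bliss")

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="rectangular"):
            DoseResponseMatrix("A", "B", "c", [1, 2, 1], [1, 1, 2], [0, 0, 0],
                               (np.ones(3), np.ones(3)), (np.ones(3), np.ones(3)))


class TestCss:
    c1 = HillCurve(0.0, 0.9, 1.0, 1.5)
    c2 = HillCurve(0.0, 0.8, 2.0, 1.2)

    def test_all_zero_responses_score_zero(self):
        m = make_matrix(self.c1, self.c2)
        m.y = np.zeros_like(m.y)
        assert css_score(m) == pytest.approx(0.0, abs=1e-9)

    def test_matches_fine_grid_trapezoid_oracle(self):
        # responses are an additive blend of two 4PLs, so each orientation's
        # slice is itself a 4PL and the fitted integral must track a dense
        # trapezoid integral of the generating blend within 1%
        g1 = self.c1.m * np.logspace(-1, 1, 5)
        g2 = self.c2.m * np.logspace(-1, 1, 5)
        m = make_matrix(self.c1, self.c2, grid1=g1, grid2=g2)
        m.y = 0.5 * hill_response(m.d1, self.c1) + 0.5 * hill_response(m.d2, self.c2)

        def oracle_orientation(free_c, pin_c, free_grid, pin_dose):
            xs = np.logspace(np.log10(free_grid.min()), np.log10(free_grid.max()), 4000)
            vals = 0.5 * hill_response(xs, free_c) + 0.5 * hill_response(pin_dose, pin_c)
            span = np.log10(free_grid.max()) - np.log10(free_grid.min())
            return np.trapezoid(vals, np.log10(xs)) / span

        # pinned partner dose = tested dose nearest its IC50 = m exactly
        oracle = 100.0 * 0.5 * (
            oracle_orientation(self.c1, self.c2, g1, self.c2.m)
            + oracle_orientation(self.c2, self.c1, g2, self.c1.m))
        assert css_score(m) == pytest.approx(oracle, rel=0.01)

    def test_flat_partner_curve_undefined(self):
        m = make_matrix(self.c1, self.c2)
        flat = np.full(5, 0.4)
        m.mono2 = (m.mono2[0], flat)
        with pytest.raises(Exception, match="flat|CSS"):
            css_score(m)


def test_score_table_rejects_duplicate_keys():
    m = make_matrix(HillCurve(0, 1, 1, 1.5), HillCurve(0, 1, 2, 1.5))
    m.y = expected_matrix(m, "bliss")
    with pytest.raises(ValueError, match="duplicate"):
        score_table([m, m], models=["bliss"])
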