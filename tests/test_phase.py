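"""Phase equation reconstruction, fixed points and bifurcation diagram."""
import numpy as np
import pytest

import myothermo as mt
from myothermo.phase import Branch, PhaseModel, Stability

# reference coefficients of the reconstructed phase equation:
# y' = 0.65 (9.046 - y) - 0.003 y'^2, with y'^2 = 6.89 G^-4.82
A_LIN, Y_INF, B_QUAD = 0.65, 9.046, 0.003
A_POW, BETA = 6.89, -4.82


def exact_pairs(yprime):
    """(y, y') pairs generated exactly from the reference equation."""
    yp = np.asarray(yprime, dtype=float)
    y = Y_INF - (yp + B_QUAD * yp ** 2) / A_LIN
    return y, yp


@pytest.fixture()
def ref_model():
    return PhaseModel(a_lin=A_LIN, y_inf=Y_INF, b_quad=B_QUAD,
                      A_pow=A_POW, beta=BETA, k_comb=B_QUAD * A_POW)


class TestFitPhaseEquation:
    def test_round_trip_reference_coefficients(self):
        y, yp = exact_pairs(np.linspace(-300, 3, 40))
        model = mt.fit_phase_equation(y, yp)
        assert model.a_lin == pytest.approx(A_LIN, rel=1e-9)
        assert model.y_inf == pytest.approx(Y_INF, rel=1e-9)
        assert model.b_quad == pytest.approx(B_QUAD, rel=1e-9)

    def test_linear_data_degenerates_gracefully(self):
        yp = np.linspace(-5, 5, 12)
        y = Y_INF - yp / A_LIN               # c2 = 0
        model = mt.fit_phase_equation(y, yp)
        assert model.b_quad == pytest.approx(0.0, abs=1e-9)
        assert model.a_lin == pytest.approx(A_LIN, rel=1e-9)

    def test_rank_error_on_identical_yprime(self):
        with pytest.raises(ValueError, match="rank"):
            mt.fit_phase_equation([1, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2])


class TestPowerLaw:
    def test_round_trip(self):
        G = np.linspace(0.3, 3.5, 20)
        A, beta = mt.fit_eep_power_law(G, A_POW * G ** BETA)
        assert A == pytest.approx(A_POW, rel=1e-9)
        assert beta == pytest.approx(BETA, rel=1e-9)

    def test_flat_law(self):
        G = np.linspace(0.5, 2.0, 10)
        A, beta = mt.fit_eep_power_law(G, np.full(10, 3.3))
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert A == pytest.approx(3.3, rel=1e-12)

    def test_underdetermined_and_domain_errors(self):
        with pytest.raises(ValueError):
            mt.fit_eep_power_law([1.0], [2.0])
        with pytest.raises(ValueError):
            mt.fit_eep_power_law([1.0, -1.0], [2.0, 2.0])


class TestCombineAndSteadyState:
    def test_combined_coefficient(self):
        model = mt.combine(PhaseModel(A_LIN, Y_INF, B_QUAD), A_POW, BETA)
        assert model.k_comb == pytest.approx(0.020670, abs=1e-6)
        assert round(model.k_comb, 2) == 0.02
        assert mt.combine(PhaseModel(A_LIN, Y_INF, 0.0), A_POW, BETA).k_comb == 0.0
        double = mt.combine(PhaseModel(A_LIN, Y_INF, B_QUAD), 2 * A_POW, BETA)
        assert double.k_comb == pytest.approx(2 * model.k_comb)

    def test_high_curvature_limit_is_y_inf(self, ref_model):
        assert mt.steady_state_branch(ref_model, 1e9) == pytest.approx(Y_INF, abs=1e-9)

    def test_value_at_unit_curvature(self):
        # with the rounded printed coefficient 0.02: 9.046 - 0.02/0.65
        printed = PhaseModel(A_LIN, Y_INF, B_QUAD, A_POW, BETA, k_comb=0.02)
        assert mt.steady_state_branch(printed, 1.0) == pytest.approx(9.0152, abs=1e-4)

    def test_monotone_increasing_in_G(self, ref_model):
        G = np.linspace(0.3, 3.5, 100)
        y = mt.steady_state_branch(ref_model, G)
        assert np.all(np.diff(y) > 0)

    def test_steady_state_is_root_of_phase_function(self, ref_model):
        for G in (0.5, 1.0, 2.0):
            y_star = mt.steady_state_branch(ref_model, G)
            resid = ref_model.a_lin * (ref_model.y_inf - y_star) \
                - ref_model.k_comb * G ** ref_model.beta
            assert abs(resid) <= 1e-9

    def test_domain_error(self, ref_model):
        with pytest.raises(ValueError):
            mt.steady_state_branch(ref_model, 0.0)


class TestPhaseCurve:
    def test_vertex_closed_form(self, ref_model):
        y_v, yp_v = mt.phase_vertex(ref_model)
        assert y_v == pytest.approx(Y_INF + 1 / (4 * A_LIN * B_QUAD), rel=1e-12)
        assert y_v == pytest.approx(137.25, abs=0.01)
        assert yp_v == pytest.approx(-1 / (2 * B_QUAD), rel=1e-12)  # -166.67

    def test_roots_at_y_inf(self, ref_model):
        roots = mt.phase_curve(ref_model, Y_INF)
        assert roots[0] == pytest.approx(0.0, abs=1e-12)
        assert roots[1] == pytest.approx(-1 / B_QUAD, rel=1e-12)    # -333.33

    def test_no_roots_beyond_vertex(self, ref_model):
        y_v, _ = mt.phase_vertex(ref_model)
        assert mt.phase_curve(ref_model, y_v + 1.0) == []

    def test_roots_agree_with_brute_force_sign_scan(self, ref_model):
        """Quadratic-formula roots against a 1e5-point sign scan of the
        phase polynomial in y'."""
        for y in (0.0, Y_INF, 50.0, 120.0):
            roots = sorted(mt.phase_curve(ref_model, y))
            yp = np.linspace(-400, 50, 100_001)
            f = B_QUAD * yp ** 2 + yp - A_LIN * (Y_INF - y)
            crossings = yp[:-1][np.sign(f[:-1]) * np.sign(f[1:]) < 0]
            assert len(roots) == len(crossings)
            for r, c in zip(roots, sorted(crossings)):
                assert abs(r - c) < 0.01

    def test_branch_signs_match_cohort_assignment(self, ref_model):
        """Lower branch is everywhere negative (self-organizing side);
        upper branch is positive below the steady state."""
        y = np.linspace(0, Y_INF - 0.1, 50)
        for yy in y:
            upper, lower = mt.phase_curve(ref_model, yy)
            assert lower < 0
            assert upper > 0


class TestFixedPoints:
    def test_upper_branch_attracting(self, ref_model):
        rep = mt.classify_fixed_point(ref_model, Y_INF, Branch.UPPER)
        assert rep.classification == Stability.ATTRACTING
        assert rep.lam == pytest.approx(-A_LIN, rel=1e-4)

    def test_vertex_half_stable(self, ref_model):
        y_v, _ = mt.phase_vertex(ref_model)
        rep = mt.classify_fixed_point(ref_model, y_v, Branch.VERTEX)
        assert rep.classification == Stability.HALF_STABLE

    def test_linear_model_single_attracting_point(self):
        lin = PhaseModel(a_lin=A_LIN, y_inf=Y_INF, b_quad=0.0)
        rep = mt.classify_fixed_point(lin, Y_INF, Branch.UPPER)
        assert rep.classification == Stability.ATTRACTING
        assert rep.lam == pytest.approx(-A_LIN, rel=1e-6)

    def test_probe_window_across_vertex_raises(self, ref_model):
        y_v, _ = mt.phase_vertex(ref_model)
        with pytest.raises(ValueError, match="branch boundary"):
            mt.classify_fixed_point(ref_model, y_v - 1e-9, Branch.UPPER, eps=1e-6)


class TestBifurcationDiagram:
    def test_knee_near_unit_curvature(self, ref_model):
        _, knee = mt.bifurcation_diagram(ref_model)
        assert 0.5 <= knee <= 1.5

    def test_plateau_is_near_flat(self):
        printed = PhaseModel(A_LIN, Y_INF, B_QUAD, A_POW, BETA, k_comb=0.02)
        table, _ = mt.bifurcation_diagram(printed)
        G, y = table[:, 0], table[:, 1]
        y1 = y[np.argmin(np.abs(G - 1.0))]
        y35 = y[np.argmin(np.abs(G - 3.5))]
        assert 0 < y35 - y1 <= 0.031

    def test_flat_branch_reports_no_knee(self):
        flat = PhaseModel(A_LIN, Y_INF, B_QUAD, A_POW, BETA, k_comb=0.0)
        table, knee = mt.bifurcation_diagram(flat)
        assert knee is None
        assert np.allclose(table[:, 1], Y_INF)
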