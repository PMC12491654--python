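"""Crossbridge model: closed forms vs numeric oracles, inversion round trips."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

import myothermo as mt
import myothermo.huxley as hx

CAE_RATES = mt.HuxleyRates(2.3, 1.0, 6.9)       # term-cohort mean kinetics
HYS_RATES = mt.HuxleyRates(2.6, 3.9, 2.6)       # non-pregnant mean kinetics


def ode_attached_fraction(rates, v, x_grid):
    """Independent numeric oracle: integrate the transport ODE.

    -v dn/dx = f(x)(1-n) - g(x) n with n(h) = 0, integrated from h down
    through 0 and into the drag region where f = 0, g = g2.
    """
    h = rates.h

    def rhs(x, n):
        if x >= 0:
            f = rates.f1 * x / h
            g = rates.g1 * x / h
        else:
            f = 0.0
            g = rates.g2
        return [-(f * (1 - n[0]) - g * n[0]) / v]

    lo = float(np.min(x_grid))
    sol = solve_ivp(rhs, [h, lo], [0.0], t_eval=np.sort(x_grid)[::-1],
                    rtol=1e-10, atol=1e-13, max_step=h / 50)
    return sol.t[::-1], sol.y[0][::-1]


class TestAttachedFraction:
    def test_isometric_fixed_point(self):
        """At v = 0 the attached fraction is f1/(f1+g1) on (0, h]."""
        x, n = mt.attached_fraction(CAE_RATES, 0.0)
        inside = (x > 0) & (x <= CAE_RATES.h)
        assert np.allclose(n[inside], 2.3 / 3.3)
        assert n[inside][0] == pytest.approx(0.697, abs=5e-4)
        assert np.all(n[~inside] == 0)

    def test_no_attachment_beyond_h(self):
        rates = mt.HuxleyRates(43.3, 10.0, 209.0)
        x, n = mt.attached_fraction(rates, 150.0, x=np.array([rates.h]))
        assert n[0] == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_vs_ode_oracle_reference_rates(self):
        rates = mt.HuxleyRates(43.3, 10.0, 209.0, h=11.0)
        xg = np.linspace(-2 * rates.h, rates.h, 201)
        _, n_closed = mt.attached_fraction(rates, 200.0, x=xg)
        _, n_ode = ode_attached_fraction(rates, 200.0, xg)
        assert np.max(np.abs(n_closed - n_ode)) < 1e-6

    def test_closed_form_vs_ode_oracle_random_rates(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            f1, g1, g2 = np.exp(rng.uniform(np.log(0.5), np.log(50), 3))
            rates = mt.HuxleyRates(f1, g1, g2, h=11.0)
            v = float(np.exp(rng.uniform(np.log(0.2), np.log(5)))) * rates.phi
            xg = np.linspace(-rates.h, rates.h, 81)
            _, n_closed = mt.attached_fraction(rates, v, x=xg)
            _, n_ode = ode_attached_fraction(rates, v, xg)
            assert np.max(np.abs(n_closed - n_ode)) < 1e-6

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            mt.attached_fraction(CAE_RATES, -1.0)


class TestForceVelocity:
    def test_normalization_and_monotonicity(self):
        v, p, vmax = mt.force_velocity(CAE_RATES)
        assert p[0] == pytest.approx(1.0)
        assert np.all(np.diff(p) < 0)
        assert p[-1] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_decreasing_random_rates(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            r = float(np.exp(rng.uniform(np.log(1e-2), np.log(1e2))))
            u = np.linspace(0, hx._u_max(r), 50)
            p = hx.force_ratio(r, u)
            assert np.all(np.diff(p) < 0)

    def test_brute_force_riemann_oracle(self):
        """Closed-form P(v)/P0 against a 1e6-slab Riemann sum of the
        spring moment integral of n(x)."""
        rates = mt.HuxleyRates(43.3, 10.0, 209.0, h=11.0)
        _, _, vmax = mt.force_velocity(rates)
        v = 0.25 * vmax
        h = rates.h
        tail = 60.0 * v / rates.g2  # negative-strain e-folding cutoff
        x = np.linspace(-tail, h, 1_000_000)
        _, n = mt.attached_fraction(rates, v, x=x)
        p_brute = np.trapezoid(n * x, x) / (rates.F1 * h ** 2 / 2.0)
        p_closed = hx.force_ratio(rates.r, v / rates.phi)
        assert p_closed == pytest.approx(p_brute, abs=1e-5)

    def test_scale_invariance(self):
        """Multiplying all rates by c scales velocities by c, leaves the
        dimensionless curve (hence G) unchanged."""
        c = 3.7
        scaled = mt.HuxleyRates(c * 2.3, c * 1.0, c * 6.9)
        _, _, vmax1 = mt.force_velocity(CAE_RATES)
        _, _, vmax2 = mt.force_velocity(scaled)
        assert vmax2 == pytest.approx(c * vmax1, rel=1e-9)
        assert scaled.r == pytest.approx(CAE_RATES.r)
        assert hx.model_curvature(scaled.r) == pytest.approx(
            hx.model_curvature(CAE_RATES.r), rel=1e-9)


class TestInversion:
    def test_curvature_monotone_in_shape_ratio(self):
        """Fitted model curvature decreases with r while the curve stays
        Hill-like (r below ~1.3; beyond, G saturates at zero)."""
        r_grid = np.geomspace(0.1, 1.2, 30)
        G = np.array([hx.model_curvature(r) for r in r_grid])
        assert np.all(np.diff(G) < 0)

    def test_round_trip_via_hill_fit(self, cfg):
        """Forward curve -> Hill fit -> curvature-match inversion recovers
        the generating rates within 2 % (noise-free)."""
        TT = 25.0
        umax = hx._u_max(CAE_RATES.r)
        rel = np.array(hx.PROTOCOL_REL_LOADS)
        u = np.array([hx._u_at_load(CAE_RATES.r, p, umax) for p in rel])
        vel = u * CAE_RATES.phi / cfg.L_ref
        fit = mt.fit_hill(rel * TT, vel, TT=TT)
        rec = mt.invert_from_hill(fit, cfg, partition=2.3 / 3.3)
        for got, want in [(rec.f1, 2.3), (rec.g1, 1.0), (rec.g2, 6.9)]:
            assert got == pytest.approx(want, rel=0.02)

    @pytest.mark.parametrize("rates", [CAE_RATES, HYS_RATES],
                             ids=["caesarean", "hysterectomy"])
    def test_full_curve_fit_round_trip(self, cfg, rates):
        """Direct curve matching is exact noise-free for both cohorts'
        mean kinetics, including the non-Hill-like regime."""
        TT = 22.0
        umax = hx._u_max(rates.r)
        rel = np.array(hx.PROTOCOL_REL_LOADS)
        u = np.array([hx._u_at_load(rates.r, p, umax) for p in rel])
        vel = u * rates.phi / cfg.L_ref
        rec = hx.fit_rates(rel * TT, vel, TT, cfg, partition=rates.F1)
        for got, want in [(rec.f1, rates.f1), (rec.g1, rates.g1),
                          (rec.g2, rates.g2)]:
            assert got == pytest.approx(want, rel=1e-4)

    def test_uninvertible_curvature_raises(self, cfg):
        load, vel = mt.hyperbola_points(0.03, 5000.0, 28.0,
                                        [0, .1, .2, .3, .5, .7, 1.0])
        fit = mt.fit_hill(load, vel, TT=28.0)
        with pytest.raises(hx.InversionError, match="outside invertible"):
            mt.invert_from_hill(fit, cfg)

    def test_degenerate_fit_inputs_rejected(self, cfg):
        fit = mt.HillFit(a=10, b=0.01, Vmax=0.02, TT=20, G=2.0, rss=0, n_points=8)
        bad = mt.HillFit(a=10, b=0.01, Vmax=-0.02, TT=20, G=2.0, rss=0, n_points=8)
        mt.invert_from_hill(fit, cfg)  # fine
        with pytest.raises(ValueError):
            mt.invert_from_hill(bad, cfg)


class TestMolecularOutputs:
    def test_kcat_formula_hysterectomy_means(self, cfg):
        """kcat = f1 g1 / (2(f1+g1)) * h/ell at the non-pregnant mean
        rates: 2.6*3.9/13 * 11/36 = 0.2383, within 15 % of 0.26."""
        fit = mt.HillFit(a=24.1, b=0.0153, Vmax=0.013, TT=20.5, G=0.85,
                         rss=0, n_points=8)
        kin = mt.molecular_outputs(HYS_RATES, fit, cfg, MC_input=2.7)
        assert kin.kcat == pytest.approx(2.6 * 3.9 / 13.0 * 11.0 / 36.0, rel=1e-12)
        assert abs(kin.kcat - 0.26) / 0.26 < 0.15

    def test_atpase_identity_exact(self, cfg):
        fit = mt.HillFit(a=24.1, b=0.0153, Vmax=0.013, TT=20.5, G=0.85,
                         rss=0, n_points=8)
        for mc in (0.5, 2.7, 7.3):
            kin = mt.molecular_outputs(HYS_RATES, fit, cfg, MC_input=mc)
            assert kin.atpase == kin.kcat * kin.MC  # exact, not approx

    def test_vanishing_attachment_limit(self, cfg):
        """f1 -> 0 sends kcat, po and atpase to zero: no attachment, no
        cycling, no force."""
        fit = mt.HillFit(a=24.1, b=0.0153, Vmax=0.013, TT=20.5, G=0.85,
                         rss=0, n_points=8)
        tiny = mt.HuxleyRates(1e-9, 3.9, 2.6)
        kin = mt.molecular_outputs(tiny, fit, cfg, MC_input=2.7)
        assert kin.kcat < 1e-9
        assert kin.po < 1e-9
        assert kin.atpase < 1e-8

    def test_time_stroke_and_scale_covariance(self, cfg):
        fit = mt.HillFit(a=10, b=0.01, Vmax=0.02, TT=20, G=2.0, rss=0, n_points=8)
        kin1 = mt.molecular_outputs(CAE_RATES, fit, cfg, MC_input=2.2)
        c = 2.0
        kin2 = mt.molecular_outputs(
            mt.HuxleyRates(c * 2.3, c * 1.0, c * 6.9), fit, cfg, MC_input=2.2)
        assert kin1.ts == pytest.approx(CAE_RATES.h / kin1.v_cb_max, rel=1e-12)
        assert kin2.v_cb_max == pytest.approx(c * kin1.v_cb_max, rel=1e-9)
        assert kin2.ts == pytest.approx(kin1.ts / c, rel=1e-9)
        assert kin2.kcat == pytest.approx(c * kin1.kcat, rel=1e-12)

    def test_mc_fallback_requires_geometry(self):
        fit = mt.HillFit(a=10, b=0.01, Vmax=0.02, TT=20, G=2.0, rss=0, n_points=8)
        cfg_nok = mt.RunConfig(seed=0)          # kappa_geom unset
        with pytest.raises(ValueError, match="kappa_geom"):
            mt.molecular_outputs(CAE_RATES, fit, cfg_nok, MC_input=None)
        cfg_ok = cfg_nok.replace(kappa_geom=0.15)
        kin = mt.molecular_outputs(CAE_RATES, fit, cfg_ok, MC_input=None)
        assert kin.MC == pytest.approx(fit.TT * 0.15 / kin.po)


class TestEfficiency:
    def test_zero_at_both_ends_interior_max(self, cfg):
        v, eff, eff_max = mt.efficiency_curve(CAE_RATES, cfg)
        assert eff[0] == 0.0
        assert eff[-1] == pytest.approx(0.0, abs=1e-6)
        assert eff_max >= eff.max() > 0
        k = int(np.argmax(eff))
        assert 0 < k < len(eff) - 1

    def test_cohort_ordering(self, cfg):
        """Peak efficiency of the slow economical term-cohort kinetics
        exceeds the non-pregnant cohort's, matching the reported ordering
        (31.1 % > 17.7 %)."""
        _, _, eff_cae = mt.efficiency_curve(CAE_RATES, cfg)
        _, _, eff_hys = mt.efficiency_curve(HYS_RATES, cfg)
        assert eff_cae > eff_hys
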