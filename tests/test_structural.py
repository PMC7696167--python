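"""Structural-model oracles: dose conversion, saturable split, IG inputs,
disposition ODE and AUC against closed-form and quadrature references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from roscopk import units
from roscopk.fastsolve import pack_params, solve_batch
from roscopk.structural import (Regimen, StructuralParams, TYPICAL_PARAMS,
                                auc_0_12, auc_inf_closed_form, f_dose,
                                ig_density, ig_mat, input_rate_met,
                                input_rate_parent, solve_profile)


class TestDoseConversion:
    @pytest.mark.parametrize("mg, expected", [
        (0.0, 0.0), (200.0, 564.2545), (800.0, 2257.0179),
    ])
    def test_mg_to_umol(self, mg, expected):
        assert units.mg_to_umol(mg, 354.45) == pytest.approx(expected, rel=1e-4)

    def test_invalid_molar_mass(self):
        with pytest.raises(ValueError):
            units.mg_to_umol(100.0, 0.0)

    def test_concentration_round_trip(self):
        x = np.array([0.0, 5.0, 123.4])
        back = units.nmol_l_to_ng_ml(units.ng_ml_to_nmol_l(x, "parent"), "parent")
        np.testing.assert_allclose(back, x, rtol=1e-14)


class TestSaturableSplit:
    def test_half_saturation_definition(self):
        assert f_dose(1190.0, 1190.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("dose_mg, expected", [(200, 0.32), (400, 0.49), (800, 0.65)])
    def test_published_fractions(self, dose_mg, expected):
        fr = f_dose(units.mg_to_umol(dose_mg), 1190.0)
        assert round(fr, 2) == expected

    def test_invalid_d50(self):
        with pytest.raises(ValueError):
            f_dose(100.0, -1.0)

    @settings(max_examples=50, deadline=None)
    @given(d1=st.floats(0.1, 1e4), d2=st.floats(0.1, 1e4),
           d50=st.floats(10.0, 1e4))
    def test_strictly_monotone_in_dose(self, d1, d2, d50):
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        assert f_dose(lo, d50) < f_dose(hi, d50)
        # and decreasing in D50 (increasing in 1/D50)
        assert f_dose(d1, d50) > f_dose(d1, d50 * 1.5)


class TestInverseGaussianInput:
    def test_degenerate_cv_limit(self):
        assert ig_mat(1.0, 1e-6) == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("t_max, cv, expected", [
        (0.676, 0.542, 1.0366), (1.716, 0.354, 2.0687),
    ])
    def test_mat_values(self, t_max, cv, expected):
        assert ig_mat(t_max, cv) == pytest.approx(expected, abs=2e-4)

    @pytest.mark.parametrize("t_max, cv", [(0.676, 0.542), (1.716, 0.354)])
    def test_mode_is_t_max(self, t_max, cv):
        t = np.linspace(1e-6, 10.0, 200001)
        d = ig_density(t, t_max, cv)
        assert t[np.argmax(d)] == pytest.approx(t_max, abs=t[1] - t[0])

    def test_density_zero_at_origin_and_normalized(self):
        assert ig_density(0.0, 1.716, 0.354) == 0.0
        assert ig_density(-1.0, 1.716, 0.354) == 0.0
        total, _ = quad(ig_density, 0, 200, args=(1.716, 0.354), limit=200)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_input_integrals_split_the_dose(self):
        reg = Regimen(400.0)
        p = TYPICAL_PARAMS
        ip, _ = quad(input_rate_parent, 0, 300, args=(reg, p), limit=300)
        im, _ = quad(input_rate_met, 0, 300, args=(reg, p), limit=300)
        fr = f_dose(reg.dose_umol, p.D50)
        assert ip == pytest.approx(fr * reg.dose_umol, rel=1e-3)
        assert im == pytest.approx((1 - fr) * reg.dose_umol, rel=1e-3)
        assert ip + im == pytest.approx(reg.dose_umol, rel=1e-3)
        assert input_rate_parent(0.0, reg, p) == 0.0

    def test_pi1_one_collapses_to_single_phase(self):
        p = TYPICAL_PARAMS.replace(pi1=1.0 - 1e-12)
        t = np.linspace(0.01, 12, 50)
        fr = f_dose(Regimen(400.0).dose_umol, p.D50)
        single = fr * Regimen(400.0).dose_umol * ig_density(t, p.T1max, p.CV1)
        np.testing.assert_allclose(input_rate_parent(t, Regimen(400.0), p),
                                   single, rtol=1e-9)


class TestProfileSolver:
    def test_zero_dose_gives_zero_profiles(self):
        prof = solve_profile(TYPICAL_PARAMS, Regimen(0.0))
        assert np.all(prof.c_parent == 0) and np.all(prof.c_met == 0)
        assert prof.auc_parent_0_12 == 0.0

    def test_closed_form_auc_infinity(self):
        grid = np.arange(0.0, 200.0 + 1e-9, 0.02)
        prof = solve_profile(TYPICAL_PARAMS, Regimen(400.0, grid=grid))
        num_p = np.trapezoid(prof.c_parent, prof.times)
        num_m = np.trapezoid(prof.c_met, prof.times)
        cf_p, cf_m = auc_inf_closed_form(TYPICAL_PARAMS, 400.0)
        assert cf_p == pytest.approx(4266.0, rel=1e-3)   # nmol·h/L
        assert cf_m == pytest.approx(7032.0, rel=1e-3)
        assert num_p == pytest.approx(cf_p, rel=5e-3)
        assert num_m == pytest.approx(cf_m, rel=5e-3)

    def test_profiles_non_negative_for_random_draws(self, rng):
        for _ in range(10):
            p = TYPICAL_PARAMS.replace(**{
                f: getattr(TYPICAL_PARAMS, f) * float(np.exp(rng.normal(0, 0.4)))
                for f in ("D50", "T1max", "dT2max", "CV1", "CV2", "V",
                          "k12", "k21", "kmet", "ke")})
            prof = solve_profile(p, Regimen(200.0))
            assert np.all(prof.c_parent >= 0) and np.all(prof.c_met >= 0)

    def test_batch_solver_matches_reference(self):
        prof = solve_profile(TYPICAL_PARAMS, Regimen(400.0))
        batch = pack_params([TYPICAL_PARAMS])
        grid, cp, cm = solve_batch(batch, np.array([units.mg_to_umol(400.0)]))
        np.testing.assert_allclose(grid, prof.times, atol=1e-12)
        # compare above 0.1% of the peak; tolerance set by the adaptive
        # reference's own rtol, not the fixed-step solver
        sel = prof.c_parent > 1e-3 * prof.c_parent.max()
        np.testing.assert_allclose(cp[0, sel], prof.c_parent[sel], rtol=2e-4)
        sel = prof.c_met > 1e-3 * prof.c_met.max()
        np.testing.assert_allclose(cm[0, sel], prof.c_met[sel], rtol=2e-4)

    def test_mass_balance_all_dose_exits_via_metabolite(self):
        grid = np.arange(0.0, 300.0 + 1e-9, 0.02)
        prof = solve_profile(TYPICAL_PARAMS, Regimen(400.0, grid=grid))
        eliminated = TYPICAL_PARAMS.ke * np.trapezoid(prof.c_met * TYPICAL_PARAMS.V,
                                                      prof.times)
        assert eliminated == pytest.approx(Regimen(400.0).dose_umol * 1000.0,
                                           rel=5e-3)


class TestAuc:
    def test_zero_curve(self):
        t = np.arange(0.0, 12.01, 0.02)
        assert auc_0_12(t, np.zeros_like(t), "parent") == 0.0

    def test_constant_curve_arithmetic(self):
        t = np.arange(0.0, 12.01, 0.02)
        val = auc_0_12(t, np.full_like(t, 100.0), "parent")
        assert val == pytest.approx(100 * 12 * 354.45 / 1000.0, rel=1e-12)

    def test_grid_refinement_stability(self):
        p, reg = TYPICAL_PARAMS, Regimen(400.0)
        coarse = solve_profile(p, Regimen(400.0, grid=np.arange(0, 12.01, 0.04)))
        fine = solve_profile(p, reg)
        assert coarse.auc_parent_0_12 == pytest.approx(fine.auc_parent_0_12,
                                                       rel=1e-3)

    def test_grid_not_covering_window_rejected(self):
        t = np.arange(0.0, 8.01, 0.02)
        with pytest.raises(ValueError):
            auc_0_12(t, np.zeros_like(t), "parent")


class TestStructuralParamsValidation:
    def test_rejects_nonpositive_and_bad_pi1(self):
        with pytest.raises(ValueError):
            TYPICAL_PARAMS.replace(V=-1.0)
        with pytest.raises(ValueError):
            TYPICAL_PARAMS.replace(pi1=1.0)

    def test_t2max_derived(self):
        assert TYPICAL_PARAMS.T2max == pytest.approx(0.676 + 1.04)
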