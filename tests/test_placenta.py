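"""Placenta-fetal transfer: permeability calibration, the closed-form
steady-state unbound ratio, its invariances, and the dynamic model."""

import numpy as np
import pytest

import fetalkpuu as fk
from conftest import ode_constant_infusion_kpuu, ode_multidose_profiles


class TestCalibration:
    @pytest.mark.parametrize(
        "papp, expected",
        [
            (8.8, 500 * 8.8 / 489.9),  # nelfinavir, LLC-PK
            (45.85, 46.80),  # efavirenz, Caco-2 mean
            (489.9, 500.0),  # calibrator identity
        ],
    )
    def test_linear_permeability_scaling(self, papp, expected):
        assert fk.calibrate_clpd(papp) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_permeability(self):
        with pytest.raises(ValueError):
            fk.calibrate_clpd(0.0)

    @pytest.mark.parametrize(
        "cl_pd, volume, expected, tol",
        [
            (8.98, 623.7, 240.0, 0.01),  # nelfinavir term
            (1.0, 1000.0, 16.667, 1e-3),  # unit arithmetic
            (6.49, 636.0, 170.0, 0.01),  # imatinib term
        ],
    )
    def test_to_intrinsic(self, cl_pd, volume, expected, tol):
        assert fk.to_intrinsic(cl_pd, volume) == pytest.approx(expected, rel=tol)

    def test_to_intrinsic_volume_domain(self):
        with pytest.raises(ValueError):
            fk.to_intrinsic(1.0, 0.0)


def _params(cl_pd, cl_eff, **kw):
    base = dict(
        cl_int_pd=cl_pd,
        cl_int_efflux=cl_eff,
        placental_volume_ml=624.0,
        fetal_volume_l=5.0,
        fu_fetal=0.014,
        fu_maternal=0.014,
    )
    base.update(kw)
    return fk.PlacentaTransferParams(**base)


class TestSteadyStateKpuu:
    @pytest.mark.parametrize(
        "cl_pd, cl_eff, expected",
        [
            (240, 350, 240 / 590),  # 0.407 -> printed 0.41
            (1480, 2200, 1480 / 3680),  # 0.402 -> printed 0.39
            (170, 320, 170 / 490),  # 0.347 -> printed 0.35
            (123.4, 0.0, 1.0),  # passive-only drugs reach unity
        ],
    )
    def test_closed_form(self, cl_pd, cl_eff, expected):
        assert fk.steady_state_kpuu(_params(cl_pd, cl_eff)) == pytest.approx(expected)

    def test_volume_cancellation(self):
        for scale in (0.25, 1.0, 4.0):
            p = _params(240, 350, placental_volume_ml=624.0 * scale)
            assert fk.steady_state_kpuu(p) == pytest.approx(240 / 590)

    def test_binding_invariance(self):
        for fu_f in (0.001, 0.014, 0.5):
            p = _params(240, 350, fu_fetal=fu_f)
            assert fk.steady_state_kpuu(p) == pytest.approx(240 / 590)

    def test_monotonicity(self):
        effs = np.linspace(0, 2000, 30)
        ks = [fk.steady_state_kpuu(_params(240, e)) for e in effs]
        assert np.all(np.diff(ks) < 0)
        pds = np.linspace(50, 2000, 30)
        ks = [fk.steady_state_kpuu(_params(p, 350)) for p in pds]
        assert np.all(np.diff(ks) > 0)


class TestDynamicEquivalence:
    def test_auc_ratio_matches_closed_form_random_sets(self, nelfinavir):
        # 50 random parameter sets: steady-state unbound AUC ratio from the
        # dynamic model equals CL_PD/(CL_PD+CL_eff) within 1e-3 relative
        rng = np.random.default_rng(42)
        reg = fk.DosingRegimen(route="oral", dose_mg=500, interval_h=12, n_doses=1)
        for _ in range(50):
            p = _params(
                cl_pd=rng.uniform(50, 2000),
                cl_eff=rng.uniform(0, 3000),
                placental_volume_ml=rng.uniform(300, 900),
                fetal_volume_l=rng.uniform(1, 8),
                fu_fetal=rng.uniform(0.005, 0.9),
            )
            m, _, f = fk.simulate_mf(nelfinavir, reg, 38, p)
            ratio = np.trapezoid(f.unbound_mg_l, f.time_h) / np.trapezoid(
                m.unbound_mg_l, m.time_h
            )
            assert ratio == pytest.approx(fk.steady_state_kpuu(p), rel=1e-3)

    def test_ode_oracle_constant_infusion(self):
        # brute-force solve_ivp integration to steady state under constant
        # maternal infusion reproduces the closed form
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = _params(
                cl_pd=rng.uniform(100, 1500),
                cl_eff=rng.uniform(0, 2500),
                fetal_volume_l=rng.uniform(2, 6),
                fu_fetal=rng.uniform(0.01, 0.5),
            )
            k = ode_constant_infusion_kpuu(cl=30.0, v_m=140.0, fu_m=0.014, params=p)
            assert k == pytest.approx(fk.steady_state_kpuu(p), rel=1e-3)

    def test_ode_oracle_multidose_profiles(
        self, nelfinavir, nelfinavir_regimen, nelfinavir_placenta
    ):
        # the matrix-exponential steady state agrees pointwise with a
        # brute-force multi-dose solve_ivp run
        t, mp_ode, uv_ode = ode_multidose_profiles(
            nelfinavir, nelfinavir_regimen, 38, nelfinavir_placenta
        )
        m, _, f = fk.simulate_mf(nelfinavir, nelfinavir_regimen, 38, nelfinavir_placenta)
        np.testing.assert_allclose(
            np.interp(t, m.time_h, m.total_mg_l), mp_ode, rtol=5e-3
        )
        np.testing.assert_allclose(
            np.interp(t, f.time_h, f.total_mg_l), uv_ode, rtol=5e-3
        )


class TestSimulateMf:
    def test_no_efflux_equilibrates_unbound(self, nelfinavir, nelfinavir_regimen):
        p = _params(240, 0.0)
        m, _, f = fk.simulate_mf(nelfinavir, nelfinavir_regimen, 38, p)
        ratio = np.trapezoid(f.unbound_mg_l, f.time_h) / np.trapezoid(
            m.unbound_mg_l, m.time_h
        )
        assert ratio == pytest.approx(1.0, abs=0.005)

    def test_infinite_efflux_kills_fetal_exposure(self, nelfinavir, nelfinavir_regimen):
        p = _params(240, 1e6)
        m, _, f = fk.simulate_mf(nelfinavir, nelfinavir_regimen, 38, p)
        assert np.trapezoid(f.total_mg_l, f.time_h) < 1e-3 * np.trapezoid(
            m.total_mg_l, m.time_h
        )

    def test_fetal_binding_decoupling(self, nelfinavir, nelfinavir_regimen):
        # at periodic steady state the unbound fetal AUC is pinned by the
        # placental mass balance, so halving fu_fetal doubles the total AUC
        # and leaves the unbound AUC unchanged (the within-interval shape
        # shifts slightly because the fetal return rate constant halves)
        _, _, f1 = fk.simulate_mf(nelfinavir, nelfinavir_regimen, 38, _params(240, 350))
        _, _, f2 = fk.simulate_mf(
            nelfinavir, nelfinavir_regimen, 38, _params(240, 350, fu_fetal=0.007)
        )
        auc = lambda p, which: np.trapezoid(getattr(p, which), p.time_h)
        assert auc(f2, "total_mg_l") == pytest.approx(
            2 * auc(f1, "total_mg_l"), rel=1e-4
        )
        assert auc(f2, "unbound_mg_l") == pytest.approx(
            auc(f1, "unbound_mg_l"), rel=1e-4
        )

    def test_total_uvmp_scales_with_fu_ratio(self, nelfinavir, nelfinavir_regimen):
        # total UV/MP = Kp,uu * fu_m / fu_f at steady state (AUC sense)
        p = _params(240, 350, fu_fetal=0.028)  # fu_m/fu_f = 0.5
        m, _, f = fk.simulate_mf(nelfinavir, nelfinavir_regimen, 38, p)
        total_ratio = np.trapezoid(f.total_mg_l, f.time_h) / np.trapezoid(
            m.total_mg_l, m.time_h
        )
        assert total_ratio == pytest.approx(0.5 * 240 / 590, rel=1e-3)


class TestUvMpProfile:
    def test_identical_profiles_give_unity(self, nelfinavir, nelfinavir_regimen):
        m, _, _ = fk.simulate_mf(nelfinavir, nelfinavir_regimen, 38, _params(240, 350))
        t, r, n_ex = fk.uv_mp_profile(m, m)
        assert n_ex == 0
        np.testing.assert_allclose(r, 1.0)

    def test_proportional_profiles(self):
        t = np.linspace(0, 12, 121)
        c = np.exp(-0.2 * t) + 0.1
        m = fk.ConcentrationProfile(t, c, fu=0.014)
        f = fk.ConcentrationProfile(t, 0.41 * c, fu=0.014, compartment="uv")
        _, r, _ = fk.uv_mp_profile(m, f)
        np.testing.assert_allclose(r, 0.41)

    def test_ratio_rises_when_maternal_decays_faster(self):
        t = np.linspace(0, 12, 121)
        m = fk.ConcentrationProfile(t, np.exp(-0.5 * t), fu=0.1)
        f = fk.ConcentrationProfile(t, 0.4 * np.exp(-0.1 * t), fu=0.1)
        _, r, _ = fk.uv_mp_profile(m, f)
        assert np.all(np.diff(r) > 0)

    def test_undefined_points_excluded_and_counted(self):
        t = np.linspace(0, 3, 4)
        m = fk.ConcentrationProfile(t, np.array([1.0, 0.0, 2.0, 0.0]), fu=0.1)
        f = fk.ConcentrationProfile(t, np.array([0.5, 0.5, 1.0, 0.5]), fu=0.1)
        kept, r, n_ex = fk.uv_mp_profile(m, f)
        assert n_ex == 2
        np.testing.assert_allclose(r, [0.5, 0.5])

    def test_fully_undefined_series_errors(self):
        t = np.linspace(0, 1, 5)
        m = fk.ConcentrationProfile(t, np.zeros_like(t), fu=0.1)
        f = fk.ConcentrationProfile(t, np.ones_like(t), fu=0.1)
        with pytest.raises(ValueError, match="undefined everywhere"):
            fk.uv_mp_profile(m, f)

    def test_mismatched_grids(self):
        m = fk.ConcentrationProfile(np.linspace(0, 1, 5), np.ones(5), fu=0.1)
        f = fk.ConcentrationProfile(np.linspace(0, 2, 5), np.ones(5), fu=0.1)
        with pytest.raises(ValueError, match="time grid"):
            fk.uv_mp_profile(m, f)
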