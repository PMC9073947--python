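"""Shared fixtures and the independent ODE oracles.

The oracles integrate the maternal-fetal mass-balance equations directly
with ``scipy.integrate.solve_ivp``, writing the fluxes out long-hand from
the parameter definitions. They share no code with the package's
matrix-exponential propagator, so agreement between the two routes is a
genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fetalkpuu as fk

UL_MIN_TO_L_H = 60.0 / 1e6


@pytest.fixture(scope="session")
def nelfinavir():
    return fk.fixture_parameters("nelfinavir")[0]


@pytest.fixture(scope="session")
def nelfinavir_placenta():
    return fk.fixture_parameters("nelfinavir")[1]


@pytest.fixture(scope="session")
def nelfinavir_regimen():
    return fk.default_regimen("nelfinavir")


@pytest.fixture(scope="session")
def noise_free_dyads(nelfinavir, nelfinavir_regimen):
    return fk.generate_dyads(
        nelfinavir,
        nelfinavir_regimen,
        cl_int_efflux=350.0,
        n=20,
        sigma_log10=0.0,
        mp_sigma_log10=0.0,
        seed=3,
    )


def _mf_rhs(cl, v_m, fu_m, params):
    """Right-hand side of the maternal-fetal amount system, fluxes written
    from first principles."""
    v_pl = params.placental_volume_ml / 1000.0
    v_f = params.fetal_volume_l
    cl_pd = params.cl_int_pd * params.placental_volume_ml * UL_MIN_TO_L_H
    cl_eff = params.cl_int_efflux * params.placental_volume_ml * UL_MIN_TO_L_H
    fu_f = params.fu_fetal

    def rhs(t, y, input_rate=0.0):
        a_m, a_pl, a_f = y
        cu_m = fu_m * a_m / v_m
        cu_pl = a_pl / v_pl
        cu_f = fu_f * a_f / v_f
        return [
            input_rate - cl * a_m / v_m - cl_pd * cu_m + (cl_pd + cl_eff) * cu_pl,
            cl_pd * cu_m - (2 * cl_pd + cl_eff) * cu_pl + cl_pd * cu_f,
            cl_pd * cu_pl - cl_pd * cu_f,
        ]

    return rhs, (v_m, v_pl, v_f, fu_m, fu_f)


def ode_constant_infusion_kpuu(cl, v_m, fu_m, params, rate=1.0, horizon_h=None):
    """Unbound fetal/maternal ratio at true steady state under a constant
    maternal infusion, by brute-force ODE integration."""
    rhs, (v_m, v_pl, v_f, fu_m, fu_f) = _mf_rhs(cl, v_m, fu_m, params)
    if horizon_h is None:
        # slowest relevant scale: maternal elimination or fetal equilibration
        cl_pd = params.cl_int_pd * params.placental_volume_ml * UL_MIN_TO_L_H
        tau_f = v_f / (cl_pd * fu_f / 1.0)
        horizon_h = 30 * max(v_m / cl, tau_f)
    sol = solve_ivp(
        rhs,
        (0.0, horizon_h),
        np.zeros(3),
        args=(rate,),
        method="LSODA",
        rtol=1e-10,
        atol=1e-14,
    )
    a_m, _, a_f = sol.y[:, -1]
    return (fu_f * a_f / v_f) / (fu_m * a_m / v_m)


def ode_multidose_profiles(drug, regimen, gw, params, body_weight_kg=70.0,
                           n_doses=40, n_eval=25):
    """Maternal and fetal total-concentration profiles over the last dosing
    interval of an oral multiple-dose run, by brute-force ODE integration
    with first-order absorption."""
    cl = fk.total_clearance(drug, gw)
    vss = drug.vss_l_kg if float(gw) == 0 else drug.vss_pregnant_l_kg
    v_m = vss * body_weight_kg
    ka = drug.ka_fed if regimen.fed else drug.ka_fasted
    f_oral = drug.f_oral_fed if regimen.fed else drug.f_oral_fasted
    rhs3, (v_m, v_pl, v_f, fu_m, fu_f) = _mf_rhs(cl, v_m, drug.fu_plasma, params)

    def rhs(t, y):
        a_g = y[0]
        core = rhs3(t, y[1:], input_rate=ka * a_g)
        return [-ka * a_g] + core

    y = np.zeros(4)
    for _ in range(n_doses - 1):
        y[0] += f_oral * regimen.dose_mg
        sol = solve_ivp(rhs, (0.0, regimen.interval_h), y, method="LSODA",
                        rtol=1e-10, atol=1e-13)
        y = sol.y[:, -1]
    y[0] += f_oral * regimen.dose_mg
    t_eval = np.linspace(0.0, regimen.interval_h, n_eval)
    sol = solve_ivp(rhs, (0.0, regimen.interval_h), y, method="LSODA",
                    rtol=1e-10, atol=1e-13, t_eval=t_eval)
    return t_eval, sol.y[1] / v_m, sol.y[3] / v_f
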