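"""Permeability-limited placenta-fetal transfer model.

The placenta is a well-stirred barrier compartment between maternal and
fetal plasma. Passive diffusion (CL_int,PD, ul/min per ml placenta) is
bidirectional and identical at the maternal-placenta and placenta-fetal
barriers; transporter-mediated efflux (CL_int,efflux) acts only placenta ->
maternal at the apical barrier, where P-gp and BCRP face maternal blood.
All transfer fluxes are driven by unbound concentrations, and neither the
placenta nor the fetus eliminates drug, so at steady state the unbound
fetal/maternal ratio has the closed form

    Kp,uu,fetal = CL_int,PD / (CL_int,PD + CL_int,efflux),

independent of placental volume, fetal volume and plasma binding.
"""

from __future__ import annotations

import numpy as np

from ._linear import dosing_profile, steady_state_profile
from .maternal import ConcentrationProfile, _maternal_system, DEFAULT_BODY_WEIGHT_KG
from .parameters import (
    CalibratorConstants,
    DosingRegimen,
    DrugParameters,
    PlacentaTransferParams,
)
from .physiology import CypActivityTable, DEFAULT_CYP_TABLE, GestationalWeek

__all__ = [
    "calibrate_clpd",
    "to_intrinsic",
    "steady_state_kpuu",
    "simulate_mf",
    "uv_mp_profile",
]

#: ul/min -> l/h
_UL_MIN_TO_L_H = 60.0 / 1e6


def calibrate_clpd(
    papp_nm_s: float, cal: CalibratorConstants = CalibratorConstants()
) -> float:
    """Placental passive-diffusion clearance (l/h) by linear permeability
    scaling against the midazolam in vivo calibrator:

        CL_PD,x = CL_PD,midazolam * P_app,x / P_app,midazolam
    """
    if papp_nm_s <= 0:
        raise ValueError("apparent permeability must be strictly positive")
    return cal.cl_pd_midazolam_l_h * papp_nm_s / cal.papp_midazolam_nm_s


def to_intrinsic(cl_pd_l_h: float, volume_ml: float) -> float:
    """Convert a whole-placenta clearance (l/h) to the intrinsic per-ml value
    (ul/min per ml placenta)."""
    if volume_ml <= 0:
        raise ValueError("placental volume must be strictly positive")
    return cl_pd_l_h / _UL_MIN_TO_L_H / volume_ml


def steady_state_kpuu(params: PlacentaTransferParams) -> float:
    """Closed-form steady-state unbound fetal/maternal concentration ratio."""
    return params.cl_int_pd / (params.cl_int_pd + params.cl_int_efflux)


def _mf_system(
    drug: DrugParameters,
    regimen: DosingRegimen,
    gw: "GestationalWeek | float",
    params: PlacentaTransferParams,
    body_weight_kg: float,
    cyps: CypActivityTable,
):
    """Assemble the 4-state [gut, maternal, placenta, fetal] amount system.

    The placental pool is treated as unbound drug in the placental water
    volume; maternal and fetal fluxes use fu * total plasma concentration.
    """
    A2, bolus2, infusion2, dur, v_m = _maternal_system(
        drug, regimen, gw, body_weight_kg, cyps
    )
    v_pl = params.placental_volume_ml / 1000.0  # l
    v_f = params.fetal_volume_l
    cl_pd = params.cl_int_pd * params.placental_volume_ml * _UL_MIN_TO_L_H  # l/h
    cl_eff = params.cl_int_efflux * params.placental_volume_ml * _UL_MIN_TO_L_H
    fu_m, fu_f = params.fu_maternal, params.fu_fetal

    A = np.zeros((4, 4))
    A[:2, :2] = A2
    A[1, 1] -= cl_pd * fu_m / v_m
    A[1, 2] += (cl_pd + cl_eff) / v_pl
    A[2, 1] += cl_pd * fu_m / v_m
    A[2, 2] -= (2 * cl_pd + cl_eff) / v_pl
    A[2, 3] += cl_pd * fu_f / v_f
    A[3, 2] += cl_pd / v_pl
    A[3, 3] -= cl_pd * fu_f / v_f

    bolus = np.zeros(4)
    bolus[:2] = bolus2
    infusion = None
    if infusion2 is not None:
        infusion = np.zeros(4)
        infusion[:2] = infusion2
    return A, bolus, infusion, dur, (v_m, v_pl, v_f)


def simulate_mf(
    drug: DrugParameters,
    regimen: DosingRegimen,
    gw: "GestationalWeek | float",
    params: PlacentaTransferParams,
    *,
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    cyps: CypActivityTable = DEFAULT_CYP_TABLE,
    dt: float = 0.1,
    washout_h: float = 0.0,
    steady_state: bool = True,
) -> tuple[ConcentrationProfile, ConcentrationProfile, ConcentrationProfile]:
    """Coupled maternal, placental and fetal concentration-time profiles.

    Returns total-concentration profiles for maternal plasma, placenta
    (unbound pool, fu = 1) and fetal (umbilical-vein) plasma. With
    ``steady_state=True`` (default) the exact periodic steady-state interval
    is returned; the time axis then measures time after the last dose.
    """
    A, bolus, infusion, dur, (v_m, v_pl, v_f) = _mf_system(
        drug, regimen, gw, params, body_weight_kg, cyps
    )
    if steady_state:
        t, X = steady_state_profile(A, bolus, infusion, dur, regimen.interval_h, dt)
    else:
        t, X = dosing_profile(
            A, bolus, infusion, dur, regimen.interval_h, regimen.n_doses, dt, washout_h
        )
    maternal = ConcentrationProfile(t, X[:, 1] / v_m, fu=params.fu_maternal)
    placental = ConcentrationProfile(
        t, X[:, 2] / v_pl, fu=1.0, compartment="placenta"
    )
    fetal = ConcentrationProfile(
        t, X[:, 3] / v_f, fu=params.fu_fetal, compartment="umbilical vein plasma"
    )
    return maternal, placental, fetal


def uv_mp_profile(
    maternal: ConcentrationProfile, fetal: ConcentrationProfile
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pointwise UV/MP total-concentration ratio.

    Returns (time, ratio, n_excluded) where points with maternal total below
    machine epsilon are excluded and counted. Raises if no point is defined.
    """
    if maternal.time_h.shape != fetal.time_h.shape or np.any(
        np.abs(maternal.time_h - fetal.time_h) > 1e-9
    ):
        raise ValueError("maternal and fetal profiles must share the time grid")
    mp = maternal.total_mg_l
    defined = mp > np.finfo(float).eps
    n_excluded = int((~defined).sum())
    if not defined.any():
        raise ValueError("UV/MP undefined everywhere: maternal profile is zero")
    ratio = fetal.total_mg_l[defined] / mp[defined]
    return maternal.time_h[defined], ratio, n_excluded
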