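"""Reduced maternal disposition model and PK endpoints.

One well-stirred disposition compartment with first-order absorption stands
in for whole-body distribution: the fetal-exposure endpoint is driven by the
maternal unbound plasma exposure, which a one-compartment model with the
correct clearance and volume reproduces exactly at steady state (AUC = F x
dose / CL for any linear model). Pregnancy enters through hepatic CYP
activity multipliers applied to the CYP-mediated clearance fractions and
through the pregnancy steady-state volume of distribution; renal, biliary
and non-CYP microsomal pathways are unchanged by gestation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linear import dosing_profile, steady_state_profile
from .parameters import DosingRegimen, DrugParameters
from .physiology import CypActivityTable, DEFAULT_CYP_TABLE, GestationalWeek, _as_gw

__all__ = [
    "ConcentrationProfile",
    "PkSummary",
    "FoldError",
    "total_clearance",
    "simulate_maternal",
    "pk_summary",
    "fold_error_check",
    "DEFAULT_BODY_WEIGHT_KG",
]

DEFAULT_BODY_WEIGHT_KG = 70.0


@dataclass
class ConcentrationProfile:
    """Total and unbound plasma concentration on a regular time grid."""

    time_h: np.ndarray
    total_mg_l: np.ndarray
    fu: float
    compartment: str = "maternal plasma"

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.total_mg_l = np.asarray(self.total_mg_l, dtype=float)
        if self.time_h.shape != self.total_mg_l.shape:
            raise ValueError("time and concentration grids differ in length")
        if np.any(self.total_mg_l < -1e-12):
            raise ValueError("negative concentrations in profile")
        self.total_mg_l = np.clip(self.total_mg_l, 0.0, None)
        if not 0 < self.fu <= 1:
            raise ValueError("fu must be in (0, 1]")

    @property
    def unbound_mg_l(self) -> np.ndarray:
        return self.fu * self.total_mg_l

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "compartment": self.compartment,
                "total_mg_l": self.total_mg_l,
                "unbound_mg_l": self.unbound_mg_l,
            }
        )


@dataclass(frozen=True)
class PkSummary:
    auc_last: float  # mg*h/l over the window
    auc_inf: float  # mg*h/l extrapolated
    cmax: float  # mg/l
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.cmax < 0 or self.auc_last < 0:
            raise ValueError("PK endpoints must be nonnegative")
        if self.auc_inf + 1e-12 < self.auc_last:
            raise ValueError("AUC_inf cannot be below AUC_last")


@dataclass(frozen=True)
class FoldError:
    ratio: float
    passed: bool
    bounds: tuple[float, float] = (0.80, 1.25)


def total_clearance(
    drug: DrugParameters,
    gw: "GestationalWeek | float",
    cyps: CypActivityTable = DEFAULT_CYP_TABLE,
) -> float:
    """Total maternal plasma clearance (l/h) at gestational week ``gw``.

    CL = CL_iv * sum(f_pathway * multiplier(pathway, gw)); the multiplier is
    the pregnancy CYP activity fold-change for CYP pathways and 1 for the
    renal, biliary and non-CYP microsomal fractions, so the nonpregnant
    result equals CL_iv exactly.
    """
    cl = 0.0
    for isoform, fm in drug.fm_cyp.items():
        cl += fm * cyps.multiplier(isoform, gw)
    cl += drug.fm_hlm_other + drug.f_bile + drug.f_renal
    return drug.cl_iv * cl


def _maternal_system(
    drug: DrugParameters,
    regimen: DosingRegimen,
    gw: "GestationalWeek | float",
    body_weight_kg: float,
    cyps: CypActivityTable,
):
    """Build (A, bolus, infusion, infusion_dur, V) for the 2-state
    [gut amount, central amount] maternal model."""
    g = _as_gw(gw)
    cl = total_clearance(drug, g, cyps)
    vss = drug.vss_l_kg if g.trimester == "nonpregnant" else drug.vss_pregnant_l_kg
    v = vss * body_weight_kg
    ka = drug.ka_fed if regimen.fed else drug.ka_fasted
    A = np.array([[-ka, 0.0], [ka, -cl / v]])
    if regimen.route == "oral":
        f = drug.f_oral_fed if regimen.fed else drug.f_oral_fasted
        bolus = np.array([f * regimen.dose_mg, 0.0])
        infusion, dur = None, 0.0
    else:
        bolus = np.zeros(2)
        dur = float(regimen.infusion_duration_h)
        infusion = np.array([0.0, regimen.dose_mg / dur])
    return A, bolus, infusion, dur, v


def simulate_maternal(
    drug: DrugParameters,
    regimen: DosingRegimen,
    gw: "GestationalWeek | float" = 0.0,
    *,
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    cyps: CypActivityTable = DEFAULT_CYP_TABLE,
    dt: float = 0.1,
    washout_h: float = 24.0,
    steady_state: bool = False,
) -> ConcentrationProfile:
    """Maternal total-plasma concentration-time profile for a regimen.

    With ``steady_state=True`` the exact periodic steady-state profile over
    one dosing interval is returned (time measured from a dose); otherwise
    the transient profile over all ``regimen.n_doses`` doses plus
    ``washout_h`` hours.
    """
    A, bolus, infusion, dur, v = _maternal_system(
        drug, regimen, gw, body_weight_kg, cyps
    )
    if steady_state:
        t, X = steady_state_profile(A, bolus, infusion, dur, regimen.interval_h, dt)
    else:
        t, X = dosing_profile(
            A, bolus, infusion, dur, regimen.interval_h, regimen.n_doses, dt, washout_h
        )
    return ConcentrationProfile(t, X[:, 1] / v, fu=drug.fu_plasma)


def pk_summary(
    profile: ConcentrationProfile, window: tuple[float, float] | None = None
) -> PkSummary:
    """Trapezoidal AUC and Cmax over a time window.

    AUC_inf adds a terminal log-linear extrapolation C_last/lambda_z, with
    lambda_z regressed on the last decaying fifth of the window; if the tail
    is not mono-exponentially decaying (e.g. constant profiles), AUC_inf
    falls back to AUC_last.
    """
    t, c = profile.time_h, profile.total_mg_l
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = window
    if not t0 < t1:
        raise ValueError(f"empty time window {window}")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(f"window {window} not covered by profile [{t[0]}, {t[-1]}]")
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    tw, cw = t[mask], c[mask]
    auc_last = float(np.trapezoid(cw, tw))
    cmax = float(cw.max())

    auc_inf = auc_last
    n_tail = max(3, len(tw) // 5)
    ct, tt = cw[-n_tail:], tw[-n_tail:]
    if np.all(ct > 0):
        slope = np.polyfit(tt, np.log(ct), 1)[0]
        if slope < 0:
            auc_inf = auc_last + float(ct[-1] / -slope)
    return PkSummary(auc_last, auc_inf, cmax, (float(t0), float(t1)))


def fold_error_check(
    predicted: float, observed: float, bounds: tuple[float, float] = (0.80, 1.25)
) -> FoldError:
    """Predicted/observed ratio and the 0.80-1.25-fold acceptance verdict."""
    if observed <= 0:
        raise ValueError("observed value must be strictly positive")
    if predicted < 0:
        raise ValueError("predicted value must be nonnegative")
    ratio = predicted / observed
    return FoldError(ratio, bounds[0] <= ratio <= bounds[1], bounds)
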