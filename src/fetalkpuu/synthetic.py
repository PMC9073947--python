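"""Synthetic study inputs: virtual-trial populations and pooled dyad data.

No individual umbilical-vein/maternal-plasma measurements from the delivery
cohorts are publicly deposited, so everything the estimation pipeline
consumes can be generated here with the statistical structure the analysis
assumes:

* :func:`generate_trial` — virtual clinical trials (10 trials x 10 subjects
  by default) with lognormal between-subject variability on clearance and
  volume, summarised as a per-time-point 5th/95th percentile envelope, as
  used for PK model validation.
* :func:`generate_dyads` — pooled steady-state delivery dyads: each pair is
  sampled at a random time within the dosing interval; the maternal
  concentration comes from an individually perturbed maternal profile and
  the UV concentration from the dynamic model UV/MP ratio at that time with
  heavy multiplicative (lognormal) residual scatter, emulating the 1-2
  orders of magnitude spread seen in pooled delivery data.

Every output embeds its generating parameters and seed (``DataFrame.attrs``
and the metadata dict), and identical spec + seed reproduce identical bytes.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .drugs import fixture_parameters, term_gestational_week
from .maternal import DEFAULT_BODY_WEIGHT_KG, simulate_maternal
from .parameters import DosingRegimen, DrugParameters, PlacentaTransferParams, PopulationSpec
from .placenta import simulate_mf, uv_mp_profile

__all__ = ["generate_trial", "generate_dyads", "fixture_parameters", "TrialSimulation"]


def _lognormal_multipliers(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


class TrialSimulation:
    """Container for a virtual-trial simulation.

    Attributes
    ----------
    profiles : pd.DataFrame
        Long table (trial, subject, time_h, total_mg_l, unbound_mg_l).
    envelope : pd.DataFrame
        Per-time-point summary: p5, p95, median, mean, geomean.
    metadata : dict
        Population spec, scenario and seed.
    """

    def __init__(self, profiles: pd.DataFrame, envelope: pd.DataFrame, metadata: dict):
        self.profiles = profiles
        self.envelope = envelope
        self.metadata = metadata
        profiles.attrs["metadata"] = metadata
        envelope.attrs["metadata"] = metadata


def generate_trial(
    pop: PopulationSpec,
    drug: DrugParameters,
    regimen: DosingRegimen,
    gw: float = 0.0,
    *,
    steady_state: bool = True,
    summary: str = "median",
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    dt: float = 0.1,
    seed: Optional[int] = None,
) -> TrialSimulation:
    """Simulate a virtual clinical trial of ``pop.n_trials * pop.n_subjects``
    subjects with lognormal between-subject variability on clearance and
    volume, and compute the 5th/95th percentile envelope.

    ``summary`` ("median" | "mean" | "geomean") selects the central line so
    predictions can be compared with whichever statistic the observed study
    reported.
    """
    if summary not in ("median", "mean", "geomean"):
        raise ValueError("summary must be 'median', 'mean' or 'geomean'")
    rng = np.random.default_rng(pop.seed if seed is None else seed)
    n = pop.n_trials * pop.n_subjects
    cl_mult = _lognormal_multipliers(rng, pop.cv_clearance, n)
    v_mult = _lognormal_multipliers(rng, pop.cv_volume, n)

    rows = []
    curves = []
    for i in range(n):
        subj = drug.model_copy(
            update={
                "cl_iv": drug.cl_iv * cl_mult[i],
                "vss_l_kg": drug.vss_l_kg * v_mult[i],
                "vss_pregnant_l_kg": drug.vss_pregnant_l_kg * v_mult[i],
            }
        )
        prof = simulate_maternal(
            subj, regimen, gw, body_weight_kg=body_weight_kg, dt=dt,
            steady_state=steady_state,
        )
        curves.append(prof.total_mg_l)
        rows.append(
            pd.DataFrame(
                {
                    "trial": i // pop.n_subjects,
                    "subject": i % pop.n_subjects,
                    "time_h": prof.time_h,
                    "total_mg_l": prof.total_mg_l,
                    "unbound_mg_l": prof.unbound_mg_l,
                }
            )
        )
    profiles = pd.concat(rows, ignore_index=True)
    C = np.array(curves)  # (n_subjects_total, n_times)
    t = rows[0]["time_h"].to_numpy()
    with np.errstate(divide="ignore"):
        geo = np.exp(np.mean(np.log(np.where(C > 0, C, np.nan)), axis=0))
    envelope = pd.DataFrame(
        {
            "time_h": t,
            "p5": np.percentile(C, 5, axis=0),
            "p95": np.percentile(C, 95, axis=0),
            "median": np.median(C, axis=0),
            "mean": C.mean(axis=0),
            "geomean": geo,
        }
    )
    envelope["central"] = envelope[summary if summary != "geomean" else "geomean"]
    metadata = {
        "population": pop.model_dump(),
        "drug": drug.name,
        "regimen": regimen.model_dump(),
        "gw": gw,
        "summary": summary,
        "seed": int(pop.seed if seed is None else seed),
        "steady_state": steady_state,
    }
    return TrialSimulation(profiles, envelope, metadata)


def generate_dyads(
    drug: DrugParameters,
    regimen: DosingRegimen,
    *,
    true_kpuu: float | None = None,
    cl_int_efflux: float | None = None,
    n: int = 40,
    sigma_log10: float = 0.30,
    mp_sigma_log10: float = 0.20,
    gw: float | None = None,
    placenta: PlacentaTransferParams | None = None,
    gw_range: tuple[float, float] | None = None,
    time_distribution: str = "uniform",
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    dt: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate pooled steady-state delivery dyads.

    Exactly one of ``true_kpuu`` and ``cl_int_efflux`` fixes the generating
    efflux clearance (``CL_eff = CL_PD (1-K)/K``). Each dyad draws a sampling
    time after the last maternal dose (uniform over the dosing interval), a
    maternal concentration perturbed by a per-pair lognormal factor
    (``mp_sigma_log10``), and a UV concentration equal to MP times the
    dynamic model UV/MP at that time times ``10**eps`` with
    ``eps ~ N(0, sigma_log10)``. With both noise terms zero every UV/MP
    equals the dynamic model ratio exactly.

    Returns a DataFrame (dyad_id, time_after_dose_h, uv_conc, mp_conc, gw)
    with the generating parameters in ``.attrs["metadata"]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if time_distribution != "uniform":
        raise ValueError("only the uniform sampling-time distribution is implemented")
    g = gw if gw is not None else term_gestational_week(drug.name)
    if placenta is None:
        placenta = fixture_parameters(drug.name, gw=g)[1]
    if (true_kpuu is None) == (cl_int_efflux is None):
        raise ValueError("give exactly one of true_kpuu or cl_int_efflux")
    if true_kpuu is not None:
        if not 0 < true_kpuu <= 1:
            raise ValueError("true_kpuu must lie in (0, 1]")
        cl_int_efflux = placenta.cl_int_pd * (1 - true_kpuu) / true_kpuu
    params = placenta.with_efflux(cl_int_efflux)

    maternal, _, fetal = simulate_mf(
        drug, regimen, g, params,
        body_weight_kg=body_weight_kg, dt=dt, steady_state=True,
    )
    t_grid, ratio, _ = uv_mp_profile(maternal, fetal)

    rng = np.random.default_rng(seed)
    times = rng.uniform(0.0, regimen.interval_h, size=n)
    mp_base = np.interp(times, maternal.time_h, maternal.total_mg_l)
    mp = mp_base * 10 ** rng.normal(0.0, mp_sigma_log10, size=n)
    uv = mp * np.interp(times, t_grid, ratio) * 10 ** rng.normal(0.0, sigma_log10, size=n)
    gws = (
        np.full(n, g)
        if gw_range is None
        else rng.uniform(gw_range[0], gw_range[1], size=n)
    )

    out = pd.DataFrame(
        {
            "dyad_id": np.arange(n),
            "time_after_dose_h": times,
            "uv_conc": uv,
            "mp_conc": mp,
            "gw": gws,
        }
    )
    out.attrs["metadata"] = {
        "drug": drug.name,
        "regimen": regimen.model_dump(),
        "gw": float(g),
        "true_kpuu": float(params.cl_int_pd / (params.cl_int_pd + params.cl_int_efflux)),
        "cl_int_pd": float(params.cl_int_pd),
        "cl_int_efflux": float(params.cl_int_efflux),
        "fu_ratio": float(params.fu_maternal / params.fu_fetal),
        "sigma_log10": float(sigma_log10),
        "mp_sigma_log10": float(mp_sigma_log10),
        "n": int(n),
        "seed": int(seed),
        "time_distribution": time_distribution,
    }
    return out
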