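"""Packaged drug parameter sets for the three efflux-substrate case studies.

Nelfinavir (P-gp substrate) carries the full published parameter table. The
printed elimination fractions sum to 102%; they are normalised by their sum
here so the pathway split is preserved proportionally and the nonpregnant
total clearance equals CL_iv exactly (raw values kept in ``provenance``).

Efavirenz (BCRP substrate) and imatinib (dual P-gp/BCRP substrate) maternal
models are *reconstructed*: their published PBPK models are external, so the
reduced-model parameters here were calibrated against the published observed
steady-state AUC/Cmax values and are flagged "reconstructed, not from paper"
in each fixture's provenance. Their placental transfer clearances are the
published per-ml values.
"""

from __future__ import annotations

from .parameters import (
    CalibratorConstants,
    DosingRegimen,
    DrugParameters,
    PlacentaTransferParams,
)
from .physiology import placental_volume

__all__ = [
    "fixture_parameters",
    "default_regimen",
    "term_gestational_week",
    "transporter_for",
    "DRUG_NAMES",
]

DRUG_NAMES = ("nelfinavir", "efavirenz", "imatinib", "midazolam-calibrator")

#: Term gestational week of the matched delivery cohorts
_TERM_GW = {"nelfinavir": 38.0, "efavirenz": 39.0, "imatinib": 38.0,
            "midazolam-calibrator": 38.0}

#: Apical efflux transporter handling each substrate
_TRANSPORTER = {"nelfinavir": "P-gp", "efavirenz": "BCRP", "imatinib": "P-gp/BCRP"}

#: Published intrinsic placental clearances at term (ul/min per ml placenta)
_PLACENTA_CL = {
    "nelfinavir": (240.0, 350.0),
    "efavirenz": (1480.0, 2200.0),
    "imatinib": (170.0, 320.0),
}

# Printed nelfinavir elimination fractions (percent); they sum to 102 and are
# normalised on construction.
_NELFINAVIR_RAW_FRACTIONS = {
    "CYP3A": 25.19,
    "CYP2C19": 15.99,
    "CYP2C9": 8.72,
    "CYP1A2": 6.30,
    "CYP2E1": 11.63,
    "CYP2D6": 10.17,
    "HLM": 12.00,
    "bile": 10.00,
    "renal": 2.00,
}


def _nelfinavir() -> DrugParameters:
    total = sum(_NELFINAVIR_RAW_FRACTIONS.values())
    f = {k: v / total for k, v in _NELFINAVIR_RAW_FRACTIONS.items()}
    return DrugParameters(
        name="nelfinavir",
        molecular_weight=567.80,
        log_p=4.07,
        ionization="diprotic base",
        pka=(6.0, 11.06),
        blood_to_plasma=1.00,
        fu_plasma=0.014,
        binding_protein="AAG",
        papp_nm_s=8.8,
        papp_assay="LLC-PK",
        solubility_mg_ml=4.50,
        vss_l_kg=2.00,
        vss_pregnant_l_kg=5.20,
        cl_iv=37.70,
        fm_cyp={k: f[k] for k in
                ("CYP3A", "CYP2C19", "CYP2C9", "CYP1A2", "CYP2E1", "CYP2D6")},
        fm_hlm_other=f["HLM"],
        f_bile=f["bile"],
        f_renal=f["renal"],
        # Absorption stand-ins for the dissolution model: F back-computed from
        # the published fed/fasted AUCs with CL_iv = 37.7 l/h; ka matched to Cmax.
        ka_fed=0.85,
        ka_fasted=1.30,
        f_oral_fed=0.8125,
        f_oral_fasted=0.148,
        provenance={
            "elimination_fractions": "published table; raw percents "
            f"{_NELFINAVIR_RAW_FRACTIONS} sum to {total:.0f}%, normalised by the sum",
            "ka/F": "reconstructed, not from paper: calibrated to published "
            "fed/fasted AUC and Cmax",
            "papp_nm_s": "LLC-PK value used for placental permeability scaling",
        },
    )


def _efavirenz() -> DrugParameters:
    return DrugParameters(
        name="efavirenz",
        molecular_weight=315.68,
        log_p=4.60,
        ionization="neutral",
        pka=(10.2,),
        blood_to_plasma=0.74,
        fu_plasma=0.006,
        binding_protein="HSA",
        papp_nm_s=45.85,
        papp_assay="Caco-2 (mean of two studies)",
        vss_l_kg=3.50,
        vss_pregnant_l_kg=3.50,
        cl_iv=8.93,
        fm_cyp={"CYP2B6": 0.77, "CYP3A": 0.13, "CYP1A2": 0.05},
        fm_hlm_other=0.04,
        f_renal=0.01,
        ka_fed=0.50,
        ka_fasted=0.50,
        f_oral_fed=1.0,
        f_oral_fasted=1.0,
        provenance={
            "maternal_model": "reconstructed, not from paper: CL/Vss/ka/F "
            "calibrated to published nonpregnant and third-trimester AUC/Cmax",
            "papp_nm_s": "published Caco-2 mean",
        },
    )


def _imatinib() -> DrugParameters:
    return DrugParameters(
        name="imatinib",
        molecular_weight=493.60,
        log_p=3.00,
        ionization="base",
        pka=(8.07,),
        blood_to_plasma=0.70,
        fu_plasma=0.05,
        binding_protein="AAG",
        papp_nm_s=6.36,
        papp_assay="MDCKII mock",
        vss_l_kg=3.20,
        vss_pregnant_l_kg=3.20,
        cl_iv=12.76,
        fm_cyp={"CYP3A": 0.28},
        fm_hlm_other=0.57,
        f_bile=0.05,
        f_renal=0.10,
        ka_fed=0.60,
        ka_fasted=0.60,
        f_oral_fed=0.95,
        f_oral_fasted=0.95,
        provenance={
            "maternal_model": "reconstructed, not from paper: CL from the "
            "published 100 mg i.v. AUC; Vss/ka/F calibrated to published oral "
            "AUC/Cmax",
            "papp_nm_s": "published MDCKII value",
        },
    )


def _midazolam() -> DrugParameters:
    cal = CalibratorConstants()
    return DrugParameters(
        name="midazolam-calibrator",
        molecular_weight=325.77,
        log_p=3.89,
        ionization="base",
        pka=(6.2,),
        blood_to_plasma=0.66,
        fu_plasma=0.032,
        binding_protein="HSA",
        papp_nm_s=cal.papp_midazolam_nm_s,
        papp_assay="Caco-2 / MDR1-MDCKI mean (calibrator)",
        vss_l_kg=1.00,
        vss_pregnant_l_kg=1.50,
        cl_iv=27.0,
        fm_cyp={"CYP3A": 0.94},
        fm_hlm_other=0.05,
        f_renal=0.01,
        provenance={
            "role": "in vivo calibrator for passive placental diffusion; "
            "maternal parameters reconstructed, not from paper",
        },
    )


_BUILDERS = {
    "nelfinavir": _nelfinavir,
    "efavirenz": _efavirenz,
    "imatinib": _imatinib,
    "midazolam-calibrator": _midazolam,
}


def term_gestational_week(name: str) -> float:
    """Term GW of the delivery cohort matched to each drug's scenario."""
    _check(name)
    return _TERM_GW[name]


def transporter_for(name: str) -> str:
    _check(name)
    return _TRANSPORTER.get(name, "passive")


def _check(name: str) -> None:
    if name not in DRUG_NAMES:
        raise KeyError(f"unknown drug {name!r}; packaged drugs: {DRUG_NAMES}")


def fixture_parameters(
    name: str, gw: float | None = None
) -> tuple[DrugParameters, PlacentaTransferParams]:
    """Packaged, schema-validated parameter set for one drug.

    ``gw`` selects the gestational week for the placental volume (defaults to
    the drug's term delivery GW). Fetal fraction unbound defaults to the
    maternal value, as the measured fetal values are not publicly available;
    the steady-state unbound ratio is invariant to this choice.
    """
    _check(name)
    drug = _BUILDERS[name]()
    g = gw if gw is not None else _TERM_GW[name]
    cl_pd, cl_eff = _PLACENTA_CL.get(name, (240.0, 0.0))
    placenta = PlacentaTransferParams(
        cl_int_pd=cl_pd,
        cl_int_efflux=cl_eff,
        placental_volume_ml=placental_volume(g),
        fetal_volume_l=5.0,
        fu_fetal=drug.fu_plasma,
        fu_maternal=drug.fu_plasma,
    )
    return drug, placenta


def default_regimen(name: str) -> DosingRegimen:
    """The steady-state dosing regimen of the matched delivery cohort."""
    _check(name)
    if name == "nelfinavir":
        return DosingRegimen(route="oral", dose_mg=1250, interval_h=12, n_doses=30, fed=True)
    if name == "efavirenz":
        return DosingRegimen(route="oral", dose_mg=600, interval_h=24, n_doses=15, fed=False)
    if name == "imatinib":
        return DosingRegimen(route="oral", dose_mg=400, interval_h=24, n_doses=15, fed=True)
    return DosingRegimen(route="iv-infusion", dose_mg=5, interval_h=24, n_doses=1,
                         infusion_duration_h=0.5)
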