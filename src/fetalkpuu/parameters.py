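"""Schema-validated parameter containers.

Pydantic models for drug-related parameters, dosing regimens, placental
transfer parameters, the midazolam permeability calibrator, and virtual-
population specifications. All units are annotated on the fields; validators
enforce the physical invariants (fractions in (0, 1], elimination-pathway
fractions summing to one, strictly positive clearances and volumes).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DrugParameters",
    "DosingRegimen",
    "PlacentaTransferParams",
    "CalibratorConstants",
    "PopulationSpec",
]

_FRACTION_SUM_TOL = (0.99, 1.01)


class DrugParameters(BaseModel):
    """One drug's physicochemical, binding, absorption and elimination
    parameters for the reduced maternal disposition model.

    Elimination is carried as the fraction of total systemic clearance
    handled by each pathway (per-CYP, other microsomal, biliary, renal);
    the fractions must sum to 1 so that the nonpregnant total clearance
    equals ``cl_iv`` exactly. Pregnancy acts only on the CYP-mediated
    fractions (through the activity multipliers) and on ``vss_pregnant``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    molecular_weight: float = Field(gt=0, description="g/mol")
    log_p: float = Field(description="octanol-water logP")
    ionization: str = Field(default="neutral", description="e.g. 'diprotic base'")
    pka: tuple[float, ...] = ()
    blood_to_plasma: float = Field(gt=0, description="B/P ratio")
    fu_plasma: float = Field(gt=0, le=1, description="fraction unbound, maternal plasma")
    binding_protein: Literal["AAG", "HSA"] = "HSA"
    papp_nm_s: float = Field(gt=0, description="apparent permeability, nm/s")
    papp_assay: str = Field(default="", description="cell system of the Papp value")
    solubility_mg_ml: Optional[float] = Field(default=None, gt=0)

    vss_l_kg: float = Field(gt=0, description="Vss, nonpregnant, l/kg")
    vss_pregnant_l_kg: float = Field(gt=0, description="Vss during pregnancy, l/kg")

    cl_iv: float = Field(gt=0, description="total systemic plasma clearance, l/h")
    fm_cyp: dict[str, float] = Field(
        default_factory=dict,
        description="fraction of total clearance via each hepatic CYP isoform",
    )
    fm_hlm_other: float = Field(
        default=0.0, ge=0, le=1,
        description="fraction via non-CYP-assigned microsomal metabolism",
    )
    f_bile: float = Field(default=0.0, ge=0, le=1, description="biliary fraction")
    f_renal: float = Field(default=0.0, ge=0, le=1, description="renal fraction")

    ka_fed: float = Field(default=1.0, gt=0, description="first-order ka, fed, 1/h")
    ka_fasted: float = Field(default=1.0, gt=0, description="first-order ka, fasted, 1/h")
    f_oral_fed: float = Field(default=1.0, gt=0, le=1, description="oral availability, fed")
    f_oral_fasted: float = Field(default=1.0, gt=0, le=1)

    provenance: dict[str, str] = Field(
        default_factory=dict,
        description="per-field source notes; 'reconstructed' flags values not "
        "taken from published tables",
    )

    @model_validator(mode="after")
    def _fractions_sum_to_one(self) -> "DrugParameters":
        total = sum(self.fm_cyp.values()) + self.fm_hlm_other + self.f_bile + self.f_renal
        lo, hi = _FRACTION_SUM_TOL
        if not lo <= total <= hi:
            raise ValueError(
                f"elimination fractions must sum to 1 (got {total:.4f}) for {self.name}"
            )
        if any(f < 0 or f > 1 for f in self.fm_cyp.values()):
            raise ValueError("each fm_cyp must lie in [0, 1]")
        return self


class DosingRegimen(BaseModel):
    """Dose route, size and schedule."""

    model_config = ConfigDict(frozen=True)

    route: Literal["iv-infusion", "oral"]
    dose_mg: float = Field(gt=0)
    interval_h: float = Field(gt=0, description="dosing interval, h")
    n_doses: int = Field(ge=1)
    infusion_duration_h: Optional[float] = Field(default=None, gt=0)
    fed: bool = Field(default=True, description="selects the fed/fasted absorption preset")

    @model_validator(mode="after")
    def _infusion_needs_duration(self) -> "DosingRegimen":
        if self.route == "iv-infusion" and self.infusion_duration_h is None:
            raise ValueError("iv-infusion regimens need infusion_duration_h")
        if self.route == "iv-infusion" and self.infusion_duration_h > self.interval_h:
            raise ValueError("infusion duration exceeds dosing interval")
        return self


class PlacentaTransferParams(BaseModel):
    """Intrinsic placental transfer clearances and compartment sizes.

    ``cl_int_pd`` is the bidirectional passive-diffusion clearance applied at
    both the maternal-placenta and placenta-fetal barriers; ``cl_int_efflux``
    acts only placenta -> maternal at the maternal-facing (apical) barrier,
    where P-gp and BCRP reside. Both are intrinsic values per ml of placenta.
    """

    model_config = ConfigDict(frozen=True)

    cl_int_pd: float = Field(gt=0, description="ul/min per ml placenta, bidirectional")
    cl_int_efflux: float = Field(ge=0, description="ul/min per ml placenta, apical efflux")
    placental_volume_ml: float = Field(gt=0)
    fetal_volume_l: float = Field(default=5.0, gt=0, description="lumped fetal pool, l")
    fu_fetal: float = Field(gt=0, le=1, description="fraction unbound, fetal plasma")
    fu_maternal: float = Field(gt=0, le=1)

    def with_efflux(self, cl_int_efflux: float) -> "PlacentaTransferParams":
        # model_validate rather than model_copy so the new value is checked
        return self.model_validate(
            {**self.model_dump(), "cl_int_efflux": float(cl_int_efflux)}
        )


class CalibratorConstants(BaseModel):
    """Midazolam in vivo calibrator for passive placental diffusion."""

    model_config = ConfigDict(frozen=True)

    papp_midazolam_nm_s: float = Field(default=489.9, gt=0)
    cl_pd_midazolam_l_h: float = Field(default=500.0, gt=0)


class PopulationSpec(BaseModel):
    """Virtual-trial population design: 10 trials x 10 subjects by default,
    lognormal between-subject variability on clearance and volume."""

    model_config = ConfigDict(frozen=True)

    n_trials: int = Field(default=10, ge=1)
    n_subjects: int = Field(default=10, ge=1, description="subjects per trial")
    age_range: tuple[float, float] = (18.0, 45.0)
    proportion_female: float = Field(default=1.0, ge=0, le=1)
    gw_range: tuple[float, float] = Field(
        default=(31.0, 41.0), description="gestational age at delivery, weeks"
    )
    cv_clearance: float = Field(default=0.30, ge=0, description="lognormal CV on CL")
    cv_volume: float = Field(default=0.20, ge=0, description="lognormal CV on V")
    sigma_log10_uvmp: float = Field(
        default=0.30, ge=0, description="residual UV/MP multiplicative noise, log10 SD"
    )
    seed: int = 0
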