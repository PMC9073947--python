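"""Scenario configuration: one YAML file per reproducible run.

A scenario names the drug (a packaged fixture or an inline parameter
mapping), the dosing regimen, the gestational week, optional placental
overrides, the estimation objective and a seed. Every command writes its
resolved configuration next to its outputs so a run can be replayed from a
single artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .drugs import DRUG_NAMES, default_regimen, fixture_parameters, term_gestational_week
from .parameters import DosingRegimen, DrugParameters, PlacentaTransferParams

__all__ = ["ScenarioConfig", "load_scenario", "resolved_config_hash"]


class PlacentaOverrides(BaseModel):
    model_config = ConfigDict(frozen=True)

    cl_int_pd: Optional[float] = Field(default=None, gt=0)
    cl_int_efflux: Optional[float] = Field(default=None, ge=0)
    placental_volume_ml: Optional[float] = Field(default=None, gt=0)
    fetal_volume_l: Optional[float] = Field(default=None, gt=0)
    fu_fetal: Optional[float] = Field(default=None, gt=0, le=1)


class ScenarioConfig(BaseModel):
    """Fully serialisable description of one simulation/estimation run."""

    model_config = ConfigDict(frozen=True)

    drug: Union[str, dict] = Field(
        description=f"packaged drug name {DRUG_NAMES} or an inline parameter mapping"
    )
    regimen: Optional[dict] = Field(
        default=None, description="DosingRegimen fields; defaults to the drug's regimen"
    )
    gw: Optional[float] = Field(default=None, description="gestational week at delivery")
    placenta: PlacentaOverrides = PlacentaOverrides()
    objective: str = Field(default="afe", pattern="^(afe|aafe)$")
    bootstrap: int = Field(default=1000, ge=0)
    body_weight_kg: float = Field(default=70.0, gt=0)
    seed: int = 0

    def resolve(self) -> tuple[DrugParameters, DosingRegimen, float, PlacentaTransferParams]:
        """Materialise (drug, regimen, gw, placenta) from the config."""
        if isinstance(self.drug, str):
            gw = self.gw if self.gw is not None else term_gestational_week(self.drug)
            drug, placenta = fixture_parameters(self.drug, gw=gw)
            regimen = (
                DosingRegimen(**self.regimen)
                if self.regimen is not None
                else default_regimen(self.drug)
            )
        else:
            drug = DrugParameters(**self.drug)
            if self.regimen is None:
                raise ValueError("inline drug definitions require an explicit regimen")
            if self.gw is None:
                raise ValueError("inline drug definitions require an explicit gw")
            regimen = DosingRegimen(**self.regimen)
            gw = self.gw
            from .physiology import placental_volume

            placenta = PlacentaTransferParams(
                cl_int_pd=self.placenta.cl_int_pd or 1.0,
                cl_int_efflux=self.placenta.cl_int_efflux or 0.0,
                placental_volume_ml=placental_volume(gw),
                fu_fetal=drug.fu_plasma,
                fu_maternal=drug.fu_plasma,
            )
        updates = {
            k: v for k, v in self.placenta.model_dump().items() if v is not None
        }
        if updates:
            placenta = placenta.model_copy(update=updates)
        return drug, regimen, gw, placenta


def load_scenario(path: "str | Path") -> ScenarioConfig:
    """Read and validate a scenario YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return ScenarioConfig(**raw)


def resolved_config_hash(cfg: ScenarioConfig) -> str:
    """Stable short hash of the resolved configuration, for run logs."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_resolved(cfg: ScenarioConfig, out_dir: "str | Path") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
    return path
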