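"""Validated YAML program configurations (pydantic models).

Each command-line program maps one YAML document onto one of these models;
unknown keys are rejected, paths are checked at load time and validation
errors are reported all at once.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .filters import CTFParams


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CTFSection(_StrictModel):
    voltage: float = Field(gt=0, description="kV")
    cs: float = Field(ge=0, description="mm")
    amplitude_contrast: float = Field(ge=0, le=1)
    defocus_u: float
    defocus_v: float
    astig_angle: float = 0.0
    phase_shift: float = 0.0
    b_factor: float = Field(default=0.0, ge=0)

    def to_params(self, pixel_size: float) -> CTFParams:
        return CTFParams(pixel_size=pixel_size, **self.model_dump())


class _ExistingPath(str):
    pass


def _check_exists(v: str) -> str:
    if not Path(v).exists():
        raise ValueError(f"path does not exist: {v}")
    return v


class SimulateVolumeConfig(_StrictModel):
    atoms_path: str
    output_mrc: str
    box_size: int = Field(ge=16)
    pixel_size: float = Field(gt=0)
    b_scale: float = Field(default=1.0, ge=0)
    extra_b: float = Field(default=0.0, ge=0)
    recenter: bool = False
    seed: Optional[int] = None

    _v = field_validator("atoms_path")(_check_exists)


class MatchTemplateConfig(_StrictModel):
    micrograph_mrc: str
    template_mrc: str
    output_dir: str
    ctf: CTFSection
    psi_step: float = Field(default=1.5, gt=0, le=180)
    theta_step: float = Field(default=2.5, gt=0, le=180)
    symmetry: str = "C1"
    defocus_min: float = -1200.0
    defocus_max: float = 1200.0
    defocus_step: float = Field(default=200.0, gt=0)
    expected_false_positives: float = Field(default=1.0, gt=0)
    exclusion_radius: Optional[int] = Field(default=None, ge=1)
    micrograph_id: Optional[str] = None
    seed: Optional[int] = None

    _v = field_validator("micrograph_mrc", "template_mrc")(_check_exists)


class RefineTemplateConfig(_StrictModel):
    micrograph_mrc: str
    template_mrc: str
    particles_csv: str
    output_csv: str
    ctf: CTFSection
    angular_step_initial: float = Field(default=0.5, gt=0)
    angular_step_final: float = Field(default=0.05, gt=0)
    defocus_range: float = Field(default=100.0, ge=0)
    defocus_step: float = Field(default=20.0, gt=0)
    position_window: int = Field(default=2, ge=0)
    noise_maps_dir: Optional[str] = None
    seed: Optional[int] = None

    _v = field_validator("micrograph_mrc", "template_mrc", "particles_csv")(_check_exists)


class OptimizeTemplateConfig(_StrictModel):
    micrograph_mrc: str
    atoms_path: str
    particles_csv: str
    output_csv: str
    ctf: CTFSection
    box_size: int = Field(ge=16)
    pixel_size: float = Field(gt=0)
    b_scale: float = Field(default=1.0, ge=0)
    extra_b: float = Field(default=0.0, ge=0)
    coarse_range: float = Field(default=0.05, gt=0)
    coarse_step: float = Field(default=0.01, gt=0)
    fine_range: float = Field(default=0.008, gt=0)
    fine_step: float = Field(default=0.001, gt=0)
    objective: Literal["top_n", "z_above"] = "top_n"
    top_n: int = Field(default=50, ge=1)
    z_min: float = 8.0
    write_individual_csv: bool = False
    noise_maps_dir: Optional[str] = None
    seed: Optional[int] = None

    _v = field_validator("micrograph_mrc", "atoms_path", "particles_csv")(_check_exists)


class ConstrainedStage(_StrictModel):
    psi: Optional[tuple[float, float, float]] = None
    theta: Optional[tuple[float, float, float]] = None
    defocus: Optional[tuple[float, float, float]] = None


class ConstrainedSearchConfig(_StrictModel):
    micrograph_mrc: str
    template2_mrc: str
    particles_csv: str          # reference (body-1) detections
    noise_maps_dir: str         # full-search maps of template2 on this micrograph
    output_csv: str
    ctf: CTFSection
    rotation_axis: tuple[float, float, float]
    center_offset: tuple[float, float, float]
    window: int = Field(default=2, ge=0)
    expected_fp: float = Field(default=1.0 / 200.0, gt=0)
    stages: Optional[list[ConstrainedStage]] = None
    rotation_threshold: float = 4.0
    seed: Optional[int] = None

    _v = field_validator("micrograph_mrc", "template2_mrc", "particles_csv",
                         "noise_maps_dir")(_check_exists)


def load_config(path, model: type[_StrictModel]):
    """Parse one YAML document into the given config model; pydantic
    reports every offending key in a single error."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return model.model_validate(doc)


def config_hash(cfg: _StrictModel) -> str:
    """Stable short hash of a validated configuration, for provenance."""
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:12]
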