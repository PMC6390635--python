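"""Run configuration: a single YAML/JSON file with per-subcommand blocks.

Validation is strict (unknown keys rejected) and exhaustive: every violation
is reported, not just the first.  Each CLI run persists the resolved
configuration next to its outputs for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsBlock(_Strict):
    d_x_mm2_per_s: float = Field(gt=0)
    d_y_mm2_per_s: float = Field(gt=0)
    d_z_mm2_per_s: float = Field(gt=0)
    k_per_s: float = Field(ge=0, default=0.0)
    alpha: float = Field(gt=0, le=1, default=1.0)


class SourceBlock(_Strict):
    kind: str = "instantaneous"
    mass_nmol: float | None = None
    c0_mM: float | None = None
    q_mm3_per_s: float | None = None
    duration_s: float | None = None
    position_mm: list[float] = Field(default=[0.0, 0.0, 0.0])
    release_time_s: float = 0.0


class PhantomBlock(_Strict):
    params: ParamsBlock | None = None
    source: SourceBlock | None = None
    kappa_mM_per_SU: float = Field(gt=0, default=0.05)
    noise_kind: str = "rician"
    noise_sigma_fraction: float = Field(ge=0, default=0.05)
    acquisition_times_s: list[float] | None = None
    voxel_size_mm: list[float] | None = None
    field_shape: list[int] | None = None
    injection_site_mm: list[float] | None = None


class SimulateBlock(_Strict):
    engine: str = "analytic"            # analytic | fd
    params: ParamsBlock
    source: SourceBlock
    half_width_mm: float = Field(gt=0, default=3.0)
    spacing_mm: float = Field(gt=0, default=0.1)
    output_times_s: list[float]


class FitBlock(_Strict):
    samples_csv: str | None = None
    image_dir: str | None = None  # directory holding pre/post NIfTI + sidecars
    multistart: int = Field(ge=1, default=8)
    amplitude_handling: str = "fit_amplitude"
    mass_nmol: float | None = None
    average_convention: str = "rss"
    d_free_mm2_per_s: float | None = None


class RecoverBlock(_Strict):
    n_reps: int = Field(ge=2, default=25)
    noise_sigma_fraction: float = Field(ge=0, default=0.05)


class MapsBlock(_Strict):
    tiles: list[int] = Field(default=[2, 2])
    parameter: str = "average_d"


class RunConfig(_Strict):
    """Top-level run configuration: global settings plus subcommand blocks."""

    seed: int = 0
    output_dir: str = "issdiff_out"
    log_level: str = "info"
    units: str = "mm_s_mM_nmol"
    phantom: PhantomBlock | None = None
    simulate: SimulateBlock | None = None
    fit: FitBlock | None = None
    recover: RecoverBlock | None = None
    maps: MapsBlock | None = None


def _format_errors(e: ValidationError) -> str:
    lines = ["configuration invalid:"]
    for err in e.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  - {loc}: {err['msg']}")
    return "\n".join(lines)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as e:
        raise ConfigError(_format_errors(e)) from e


def dump_config(cfg: RunConfig, path) -> None:
    """Persist the resolved configuration (YAML) alongside run outputs."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
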