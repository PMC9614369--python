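"""Run configuration: schema-validated, with defaults, round-trippable.

Configurations are plain YAML/JSON mappings validated by pydantic models
(unknown keys rejected, offending key named on error) and convert to the
runtime objects of the other modules via `config_to_objects`.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import MapTiling, tile_maps
from .plasticity import LearningConfig
from .scaffold import ScaffoldConfig
from .stimulus import Grating

__all__ = ["RunConfig", "load_config", "save_config", "config_to_objects"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SheetSettings(_Strict):
    width: float = 1.0  # mm
    height: float = 1.0  # mm
    map_spacing: float = 1.0  # mm between local-map centres
    jitter: float = 0.0  # mm, centre jitter (<= spacing/4)
    map_radius: float | None = None  # mm; default 0.45 * spacing
    p_prime: tuple[float, float] = (-0.25, 0.0)  # complex scale-rotation
    n: int = 2

    @field_validator("width", "height", "map_spacing")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v


class ScaffoldSettings(_Strict):
    n_azimuths: int = 8
    n_rings: int = 3
    bend: float = 0.35
    nu: float = 300.0  # mm/s
    n_inhibitory: int = 4

    @field_validator("nu")
    @classmethod
    def _nu_positive(cls, v):
        if v <= 0:
            raise ValueError("nu must be positive")
        return v


class GratingSettings(_Strict):
    K: float  # cycles/mm
    V: float  # mm/s
    orientation: float  # rad
    phase: float = 0.0
    profile: str = "sine"

    @field_validator("K", "V")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v


class LearningSettings(_Strict):
    lambda_tolerance: float = 0.05
    eta_bi: float = 0.3
    eta_uni: float = 0.15
    epsilon_rate: float = 0.1
    epochs: int = 10
    C_range: float = 1.0
    singularity_radius: float = 0.02
    establish_epochs: int = 3
    g_max: float = 10.0
    wta_sigma: float = 1.0
    hsfp_prior: float = 0.5
    V_ref: float = 3000.0
    surrogate_rate: float = 20.0
    surrogate_duration: float = 20.0
    surrogate_bin: float = 0.01


class RunConfig(_Strict):
    sheet: SheetSettings = Field(default_factory=SheetSettings)
    scaffold: ScaffoldSettings = Field(default_factory=ScaffoldSettings)
    learning: LearningSettings = Field(default_factory=LearningSettings)
    gratings: list[GratingSettings] = Field(default_factory=list)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig(**(data or {}))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_to_objects(cfg: RunConfig) -> tuple[MapTiling, ScaffoldConfig, LearningConfig, list[Grating]]:
    """Instantiate runtime objects from a validated configuration."""
    tiling = tile_maps(
        cfg.sheet.width,
        cfg.sheet.height,
        cfg.sheet.map_spacing,
        seed=cfg.seed,
        jitter=cfg.sheet.jitter,
        p_prime=complex(*cfg.sheet.p_prime),
        n=cfg.sheet.n,
        map_radius=cfg.sheet.map_radius,
    )
    scfg = ScaffoldConfig(
        n_azimuths=cfg.scaffold.n_azimuths,
        n_rings=cfg.scaffold.n_rings,
        bend=cfg.scaffold.bend,
        nu=cfg.scaffold.nu,
        n_inhibitory=cfg.scaffold.n_inhibitory,
    )
    lcfg = LearningConfig(seed=cfg.seed, **cfg.learning.model_dump())
    ensemble = [
        Grating(K=g.K, V=g.V, orientation=g.orientation, phase=g.phase, profile=g.profile)
        for g in cfg.gratings
    ]
    return tiling, scfg, lcfg, ensemble
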