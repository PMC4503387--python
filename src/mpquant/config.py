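"""Run configuration: a single validated YAML file with per-stage sections.

Defaults encode the study design: 30-min sampling over 49 frames for
migration, a 400-μm pattern with 15-μm annuli and a 100-μm centre/perimeter
threshold, μ > 5 μm²/min for "biased" migration, and 20 frames/s video for
contraction analysis.  Validation reports every violation at once.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

from .exceptions import ConfigurationError


class GeometrySection(BaseModel):
    diameter: float = Field(400.0, gt=0)
    centre: tuple[float, float] = (0.0, 0.0)
    annulus_width: float = Field(15.0, gt=0)


class TracksSection(BaseModel):
    dt: float = Field(30.0, gt=0)                      # min
    radial_threshold: float = Field(100.0, gt=0)       # μm
    mu_threshold: float = Field(5.0, ge=0)             # μm²/min
    gof_threshold: float = Field(0.3, gt=0)
    max_lag_fraction: float = Field(1 / 3, gt=0, le=1)


class ContractionSection(BaseModel):
    frame_rate: float = Field(20.0, gt=0)              # frames/s
    pixel_size: float = Field(1.0, gt=0)               # μm/pixel
    block_size: int = Field(16, ge=4)
    search_radius: int = Field(8, ge=1)
    step: int = Field(8, ge=1)
    min_std: float = Field(5.0, ge=0)
    min_prominence: float = Field(0.25, gt=0, le=1)
    min_separation: float = Field(0.1, gt=0)           # s
    min_peak_speed: float = Field(1.0, ge=0)           # μm/s


class RunConfig(BaseModel):
    geometry: GeometrySection = GeometrySection()
    tracks: TracksSection = TracksSection()
    contraction: ContractionSection = ContractionSection()
    seed: int = 0
    stages: list[str] = ["tracks", "spatial", "contraction"]
    output_dir: str = "results"

    def canonical_dict(self) -> dict:
        return self.model_dump(mode="json")


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults.

    Raises :class:`ConfigurationError` listing every invalid field at once.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("<root>", "config must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError("config", problems) from exc


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.canonical_dict(), sort_keys=True)
    )
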