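"""Experiment configuration: one human-readable YAML file drives a full
run. Every threshold defaults to the validation protocol's standard value
(four ground photons per 30 m cell, sensitivity 0.9, 100 m x 12 m and 25 m
buffers, 30 m unified grid); changing any requires an explicit entry."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .scene import SceneConfig

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    extent: tuple[float, float, float, float] = (0.0, 0.0, 300.0, 300.0)
    cell_size: float = 1.0          # truth raster resolution (m)
    grid_cell: float = 30.0         # unified grid cell (m)
    min_ground_photons: int = 4
    rh_j: int = 90
    veg_threshold: float = 2.0      # m, CHM vegetation mask
    min_sensitivity: float = 0.9
    buffer_length: float = 100.0
    buffer_width: float = 12.0
    footprint_diameter: float = 25.0
    track_azimuth: float = 0.0
    gedi_spacing: float = 60.0
    search_diameter: float = 25.0
    search_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.scene, dict):
            self.scene = SceneConfig(**self.scene)
        self.extent = tuple(float(v) for v in self.extent)
        self.scene.seed = int(self.seed)

    def validate(self) -> "ExperimentConfig":
        positive = ("cell_size", "grid_cell", "buffer_length", "buffer_width",
                    "footprint_diameter", "gedi_spacing", "search_diameter",
                    "search_step")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field '{name}' must be > 0, "
                                 f"got {getattr(self, name)}")
        if self.min_ground_photons < 1:
            raise ValueError("config field 'min_ground_photons' must be >= 1")
        if not (0 < self.rh_j <= 100):
            raise ValueError("config field 'rh_j' must lie in (0, 100]")
        self.scene.validate()
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
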