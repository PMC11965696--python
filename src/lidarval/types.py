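"""Shared domain containers: point clouds, photon tables, footprint records.

Class-code conventions follow the field's products: LAS classes 2 (ground)
and 5 (high vegetation) for discrete returns; photon classes 0..3
(noise / ground / canopy / top of canopy) for photon-counting data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LAS_GROUND", "LAS_VEGETATION",
    "PHOTON_NOISE", "PHOTON_GROUND", "PHOTON_CANOPY", "PHOTON_TOC",
    "PHOTON_CLASS_NAMES",
    "PointCloud", "PhotonTable", "FootprintRecord",
]

LAS_GROUND = 2
LAS_VEGETATION = 5

PHOTON_NOISE = 0
PHOTON_GROUND = 1
PHOTON_CANOPY = 2
PHOTON_TOC = 3

PHOTON_CLASS_NAMES = {
    PHOTON_NOISE: "noise",
    PHOTON_GROUND: "ground",
    PHOTON_CANOPY: "canopy",
    PHOTON_TOC: "top_of_canopy",
}


@dataclass
class PointCloud:
    """Classified discrete-return point cloud (airborne reference data)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray
    classification: np.ndarray  # LAS codes: 2 ground, 5 vegetation

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.classification = np.asarray(self.classification, dtype=np.uint8)
        n = len(self.x)
        for arr in (self.y, self.z, self.intensity, self.classification):
            if len(arr) != n:
                raise ValueError("point cloud arrays must share length")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                      and np.isfinite(self.z).all()):
            raise ValueError("point coordinates must be finite")
        if n and not (self.intensity > 0).all():
            raise ValueError("intensities must be positive")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.x[mask], self.y[mask], self.z[mask],
                          self.intensity[mask], self.classification[mask])

    @property
    def ground(self) -> "PointCloud":
        return self.subset(self.classification == LAS_GROUND)

    @property
    def vegetation(self) -> "PointCloud":
        return self.subset(self.classification == LAS_VEGETATION)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "z": self.z,
                             "intensity": self.intensity,
                             "classification": self.classification})


@dataclass
class PhotonTable:
    """Photon-counting data with segment/classification linkage.

    ``photons`` is the geolocated-photon table (one row per photon, in
    along-track order, 1-based ``photon_index``); ``records`` carries the
    classification linkage rows (``ph_segment_id``, ``ph_index_beg``,
    ``classed_pc_indx``, ``classification``); ``segments`` holds per-segment
    nominal centers. The generator also writes ``truth_class`` (and
    ``x_true``/``y_true`` when geolocation error is injected) into
    ``photons`` so downstream stages can be checked against ground truth.
    """

    photons: pd.DataFrame
    records: pd.DataFrame
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        req = {"photon_index", "x", "y", "z"}
        missing = req - set(self.photons.columns)
        if missing:
            raise ValueError(f"photon table missing columns: {sorted(missing)}")
        if len(self.records):
            req = {"ph_segment_id", "ph_index_beg", "classed_pc_indx",
                   "classification"}
            missing = req - set(self.records.columns)
            if missing:
                raise ValueError(
                    f"linkage records missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.photons)


@dataclass
class FootprintRecord:
    """One full-waveform footprint: reported/true geometry, product values,
    quality fields, and the attached received waveform."""

    footprint_id: int
    x: float                      # reported center
    y: float
    x_true: float                 # truth (known to the generator)
    y_true: float
    elev_lowestmode: float
    rh: dict                      # percentile j -> relative height (m)
    sensitivity: float = 1.0
    degrade_flag: int = 0
    quality_flag: int = 1
    rx_assess_flag: int = 0
    waveform: Optional[object] = None  # waveform.Waveform

    @property
    def true_offset(self) -> tuple[float, float]:
        """(dx, dy) from reported to true center."""
        return (self.x_true - self.x, self.y_true - self.y)
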