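"""Reference-value extraction at product footprints.

Builds the buffer zone matching each product's sampling geometry (100 m x
12 m track-aligned rectangles for photon-counting segments, 25 m circles
for full-waveform footprints), extracts mean ground elevation and canopy
relative-height percentiles (RH_j) from the airborne DEM/CHM rasters, and
applies the footprint quality filter.

The percentile rule is the sort-and-index definition: canopy heights CH are
sorted ascending into DH and RH_j = DH(i) with i = 0.01 * j * n rounded
half-up and clamped to [1, n].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely

from .raster import Raster

__all__ = [
    "BufferZone", "QualityFilterSpec",
    "track_azimuth", "make_buffer", "buffer_cell_values",
    "mean_ground_elevation", "rh_percentile", "canopy_rh",
    "buffer_mean_slope", "filter_footprints",
]

VEGETATION_CHM_THRESHOLD = 2.0  # m; CHM above this counts as vegetated


@dataclass
class BufferZone:
    """A track-aligned rectangle or an isotropic circle around a center."""

    shape: str                      # "rectangle" | "circle"
    center: tuple[float, float]
    azimuth: float = 0.0            # degrees clockwise from north
    length: float = 100.0           # rectangle, along-track (m)
    width: float = 12.0             # rectangle, cross-track (m)
    diameter: float = 25.0          # circle (m)

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle"):
            raise ValueError(f"unknown buffer shape {self.shape!r}")

    @property
    def polygon(self):
        cx, cy = self.center
        if self.shape == "circle":
            return shapely.Point(cx, cy).buffer(self.diameter / 2.0, 128)
        a = math.radians(self.azimuth)
        ux, uy = math.sin(a), math.cos(a)          # along-track unit vector
        vx, vy = math.cos(a), -math.sin(a)         # cross-track unit vector
        hl, hw = self.length / 2.0, self.width / 2.0
        corners = [(cx + sx * hl * ux + sy * hw * vx,
                    cy + sx * hl * uy + sy * hw * vy)
                   for sx, sy in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
        return shapely.Polygon(corners)

    def contains_xy(self, x, y) -> np.ndarray:
        """Strict-interior membership test (boundary points excluded)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "circle":
            cx, cy = self.center
            r = self.diameter / 2.0
            return (x - cx) ** 2 + (y - cy) ** 2 < r * r
        return shapely.contains_xy(self.polygon, x, y)


def track_azimuth(segment_centers: Sequence[tuple[float, float]]) -> float:
    """Track inclination from the first to the last segment centroid,
    degrees clockwise from north in [0, 360)."""
    centers = np.asarray(segment_centers, dtype=float)
    if len(centers) < 2:
        raise ValueError("need at least two segment centers")
    dx = centers[-1, 0] - centers[0, 0]
    dy = centers[-1, 1] - centers[0, 1]
    if dx == 0 and dy == 0:
        raise ValueError("track endpoints coincide: azimuth undefined")
    return math.degrees(math.atan2(dx, dy)) % 360.0


def make_buffer(center: tuple[float, float], shape: str = "rectangle",
                azimuth: float = 0.0, length: float = 100.0,
                width: float = 12.0, diameter: float = 25.0) -> BufferZone:
    return BufferZone(shape=shape, center=center, azimuth=azimuth,
                      length=length, width=width, diameter=diameter)


def buffer_cell_values(raster: Raster, buffer: BufferZone) -> np.ndarray:
    """Values of raster cells whose centers lie strictly inside the buffer.

    Only the buffer's bounding box is scanned; NaN cells are dropped.
    """
    minx, miny, maxx, maxy = buffer.polygon.bounds
    xs = raster.x_centers()
    ys = raster.y_centers()
    ci = np.where((xs >= minx) & (xs <= maxx))[0]
    ri = np.where((ys >= miny) & (ys <= maxy))[0]
    if len(ci) == 0 or len(ri) == 0:
        return np.empty(0)
    xx, yy = np.meshgrid(xs[ci], ys[ri])
    inside = buffer.contains_xy(xx.ravel(), yy.ravel())
    vals = raster.data[np.ix_(ri, ci)].ravel()[inside]
    return vals[np.isfinite(vals)]


def mean_ground_elevation(dem: Raster, buffer: BufferZone) -> float:
    """Hmean: arithmetic mean of DEM cells inside the buffer."""
    vals = buffer_cell_values(dem, buffer)
    if len(vals) == 0:
        raise ValueError("buffer intersects no valid DEM cells")
    return float(np.mean(vals))


def rh_percentile(values: Iterable[float], j: float) -> float:
    """RH_j of a canopy-height sample by the sort-and-index rule.

    i = 0.01 * j * n, rounded half-up, clamped to [1, n]; returns the i-th
    smallest value (1-based).
    """
    dh = np.sort(np.asarray(list(values), dtype=float))
    n = len(dh)
    if n == 0:
        raise ValueError("RH undefined on an empty sample")
    i = int(math.floor(0.01 * j * n + 0.5))
    i = min(max(i, 1), n)
    return float(dh[i - 1])


def canopy_rh(chm: Raster, buffer: BufferZone, j: float,
              veg_threshold: float = VEGETATION_CHM_THRESHOLD) -> float:
    """Reference RH_j over vegetated CHM cells (CHM > veg_threshold) whose
    centers fall in the buffer. Raises when no cell is vegetated."""
    vals = buffer_cell_values(chm, buffer)
    vals = vals[vals > veg_threshold]
    if len(vals) == 0:
        raise ValueError("no vegetated cells in buffer: RH undefined")
    return rh_percentile(vals, j)


def buffer_mean_slope(slope: Raster, buffer: BufferZone) -> float:
    vals = buffer_cell_values(slope, buffer)
    if len(vals) == 0:
        return float("nan")
    return float(np.mean(vals))


@dataclass
class QualityFilterSpec:
    """Footprint quality criteria; defaults are the product's standard
    thresholds (valid waveform, non-degraded pointing, sensitivity >= 0.9,
    clean waveform assessment)."""

    require_quality_flag: int = 1
    require_degrade_flag: int = 0
    min_sensitivity: float = 0.9
    require_rx_assess_flag: int = 0


def filter_footprints(footprints: Iterable, spec: QualityFilterSpec | None = None):
    """Apply the quality filter; returns (retained, tally).

    ``tally`` counts failures per criterion; a footprint missing any of the
    four fields is rejected under ``missing_field``.
    """
    spec = spec or QualityFilterSpec()
    tally = {"quality_flag": 0, "degrade_flag": 0, "sensitivity": 0,
             "rx_assess_flag": 0, "missing_field": 0}
    retained = []
    fields = ("quality_flag", "degrade_flag", "sensitivity", "rx_assess_flag")
    for fp in footprints:
        vals = {}
        missing = False
        for name in fields:
            v = getattr(fp, name, None)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                missing = True
            vals[name] = v
        if missing:
            tally["missing_field"] += 1
            continue
        ok = True
        if vals["quality_flag"] != spec.require_quality_flag:
            tally["quality_flag"] += 1
            ok = False
        if vals["degrade_flag"] != spec.require_degrade_flag:
            tally["degrade_flag"] += 1
            ok = False
        if vals["sensitivity"] < spec.min_sensitivity:
            tally["sensitivity"] += 1
            ok = False
        if vals["rx_assess_flag"] != spec.require_rx_assess_flag:
            tally["rx_assess_flag"] += 1
            ok = False
        if ok:
            retained.append(fp)
    return retained, tally
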