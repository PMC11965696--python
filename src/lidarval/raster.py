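"""Minimal regular-grid raster container.

Conventions: row-major arrays, row 0 at the top (north); the origin is the
upper-left *corner* of the upper-left cell; cell values refer to cell
centers. All coordinates are planar meters (projected CRS assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Raster"]


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values; NaN marks nodata.
    origin : (float, float)
        (x, y) of the upper-left corner of the grid.
    cell_size : float
        Edge length of a square cell, meters.
    """

    data: np.ndarray
    origin: tuple[float, float]
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not np.isfinite(self.cell_size) or self.cell_size <= 0:
            raise ValueError("cell_size must be a positive finite number")

    # -- geometry -----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        x0, y0 = self.origin
        return (x0, y0 - self.nrows * self.cell_size,
                x0 + self.ncols * self.cell_size, y0)

    def x_centers(self) -> np.ndarray:
        x0, _ = self.origin
        return x0 + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        _, y0 = self.origin
        return y0 - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing (x, y); half-open membership
        [edge, edge + cell_size) in x and (edge - cell_size, edge] in y."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def sample(self, x, y):
        """Nearest-cell value at planar coordinates; NaN outside the grid."""
        row, col = self.cell_of(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out[ok] = self.data[row[ok], col[ok]]
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out[0])
        return out

    # -- I/O (ESRI ASCII grid: plain-text interchange) ----------------------
    def to_ascii(self, path, nodata: float = -9999.0) -> None:
        xmin, ymin, _, _ = self.bounds
        data = np.where(np.isfinite(self.data), self.data, nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {xmin}\n"
            f"yllcorner {ymin}\n"
            f"cellsize {self.cell_size}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.6f")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", -9999.0)
        data[data == nodata] = np.nan
        cell = meta["cellsize"]
        origin = (meta["xllcorner"], meta["yllcorner"] + meta["nrows"] * cell)
        return cls(data=data, origin=origin, cell_size=cell)
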