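"""Photon-counting product processing: classification linkage and 30 m
DEM/CHM gridding.

Linkage: classified records carry (ph_segment_id, ph_index_beg,
classed_pc_indx); the global photon index in the geolocated-photon table is
``classed_pc_indx + ph_index_beg - 1`` (all indices 1-based). Photons
without a classified record keep class noise.

Gridding: ground elevation per 30 m cell is the mean ground-photon height
(cells with fewer than four ground photons are invalid); canopy heights are
computed relative to the cell's mean ground height and summarized as RH
percentiles; a CHM cell is valid only when ground, canopy, and
top-of-canopy photons are all present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import rh_percentile
from .types import (PHOTON_CANOPY, PHOTON_GROUND, PHOTON_NOISE, PHOTON_TOC,
                    PhotonTable)

__all__ = [
    "GriddedProduct", "link_atl08_to_atl03", "lattice_indices",
    "grid_ground_elevation", "grid_canopy_heights", "grid_photon_products",
    "segment_products", "DEFAULT_MIN_GROUND_PHOTONS", "DEFAULT_RH_LEVELS",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_GROUND_PHOTONS = 4
DEFAULT_RH_LEVELS = (80, 85, 90, 95, 98, 100)


@dataclass
class GriddedProduct:
    """Per-cell photon-derived layers on a snapped regular grid.

    ``cells`` has one row per nonempty cell: cell indices and center
    coordinates, per-class photon counts, mean ground elevation (``dem``),
    RH percentile layers (``rh<j>``, relative heights), validity flags, and
    the count of negative relative heights (photons below the local ground
    mean; kept, flagged).
    """

    cells: pd.DataFrame
    origin: tuple[float, float]   # lower-left corner of cell (0, 0)
    cell_size: float = 30.0


def link_atl08_to_atl03(atl03_photons: pd.DataFrame,
                        atl08_records: pd.DataFrame) -> tuple[PhotonTable, pd.DataFrame]:
    """Attach classifications to geolocated photons via the linkage formula.

    Returns (table, skipped): ``table.photons`` gains a ``classification``
    column (unmatched photons keep noise); ``skipped`` lists records whose
    computed global index falls outside the photon table, with a reason.
    """
    photons = atl03_photons.copy().reset_index(drop=True)
    n = len(photons)
    cls = np.full(n, PHOTON_NOISE, dtype=int)

    beg = atl08_records["ph_index_beg"].to_numpy()
    idx = atl08_records["classed_pc_indx"].to_numpy()
    if len(beg) and (beg.min() < 1 or idx.min() < 1):
        raise ValueError("linkage indices must be 1-based (>= 1)")
    global_idx = idx + beg - 1
    ok = (global_idx >= 1) & (global_idx <= n)
    skipped = atl08_records.loc[~ok].copy()
    if len(skipped):
        skipped["reason"] = "index_out_of_bounds"
        logger.warning("linkage: %d record(s) skipped (index out of bounds)",
                       len(skipped))
    cls[global_idx[ok] - 1] = atl08_records["classification"].to_numpy()[ok]
    photons["classification"] = cls
    table = PhotonTable(photons=photons, records=atl08_records.copy())
    return table, skipped


def lattice_indices(x, y, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Global half-open lattice cell indices: cell k spans
    [k * cell, (k + 1) * cell). Snapping to multiples of the cell size makes
    grids from different data sources align on the same cells."""
    ix = np.floor(np.asarray(x) / cell_size).astype(int)
    iy = np.floor(np.asarray(y) / cell_size).astype(int)
    return ix, iy


def grid_photon_products(photons: pd.DataFrame, cell_size: float = 30.0,
                         min_ground: int = DEFAULT_MIN_GROUND_PHOTONS,
                         rh_levels=DEFAULT_RH_LEVELS,
                         class_column: str = "classification") -> GriddedProduct:
    """Compute DEM and CHM layers on a snapped grid in one pass.

    Cell membership is half-open [edge, edge + cell) in both axes, so every
    photon falls in exactly one cell.
    """
    if class_column not in photons.columns:
        raise ValueError("photons must carry classes "
                         f"(missing column {class_column!r})")
    df = photons
    if len(df) == 0:
        return GriddedProduct(cells=pd.DataFrame(), origin=(0.0, 0.0),
                              cell_size=cell_size)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    z = df["z"].to_numpy(float)
    cls = df[class_column].to_numpy(int)
    ix, iy = lattice_indices(x, y, cell_size)

    rows = []
    work = pd.DataFrame({"ix": ix, "iy": iy, "z": z, "cls": cls})
    for (cix, ciy), grp in work.groupby(["ix", "iy"], sort=True):
        gz = grp.loc[grp["cls"] == PHOTON_GROUND, "z"].to_numpy()
        vz = grp.loc[grp["cls"].isin((PHOTON_CANOPY, PHOTON_TOC)), "z"].to_numpy()
        n_toc = int((grp["cls"] == PHOTON_TOC).sum())
        n_canopy = int((grp["cls"] == PHOTON_CANOPY).sum())
        row = {
            "ix": cix, "iy": ciy,
            "x_center": (cix + 0.5) * cell_size,
            "y_center": (ciy + 0.5) * cell_size,
            "n_ground": len(gz), "n_canopy": n_canopy, "n_toc": n_toc,
            "n_photons": len(grp),
        }
        ground_mean = float(np.mean(gz)) if len(gz) else float("nan")
        row["dem"] = ground_mean if len(gz) >= min_ground else float("nan")
        row["valid_dem"] = len(gz) >= min_ground
        valid_chm = len(gz) >= 1 and n_canopy >= 1 and n_toc >= 1
        row["valid_chm"] = valid_chm
        if valid_chm:
            rel = vz - ground_mean
            row["n_negative_rel"] = int((rel < 0).sum())
            for j in rh_levels:
                row[f"rh{j}"] = rh_percentile(rel, j)
        else:
            row["n_negative_rel"] = 0
            for j in rh_levels:
                row[f"rh{j}"] = float("nan")
        rows.append(row)
    cells = pd.DataFrame(rows)
    origin = (cells["ix"].min() * cell_size, cells["iy"].min() * cell_size)
    return GriddedProduct(cells=cells, origin=origin, cell_size=cell_size)


def grid_ground_elevation(photons: pd.DataFrame, cell_size: float = 30.0,
                          min_ground: int = DEFAULT_MIN_GROUND_PHOTONS,
                          **kw) -> GriddedProduct:
    """DEM layer only (mean ground-photon elevation per valid cell)."""
    return grid_photon_products(photons, cell_size=cell_size,
                                min_ground=min_ground, **kw)


def grid_canopy_heights(photons: pd.DataFrame, cell_size: float = 30.0,
                        rh_levels=DEFAULT_RH_LEVELS, **kw) -> GriddedProduct:
    """CHM layers only (RH percentiles of relative canopy heights)."""
    return grid_photon_products(photons, cell_size=cell_size,
                                rh_levels=rh_levels, **kw)


def segment_products(table: PhotonTable, rh_levels=DEFAULT_RH_LEVELS,
                     class_column: str = "classification") -> pd.DataFrame:
    """Footprint-scale (per 100 m segment) product values.

    Per segment: reported center (mean of signal-photon coordinates),
    terrain height = mean ground-photon elevation, and RH percentiles of
    canopy heights relative to it. Segments lacking ground photons get NaN
    terrain; segments lacking any of ground/canopy/top-of-canopy get NaN RH.
    """
    df = table.photons
    if class_column not in df.columns:
        raise ValueError(f"photons must carry classes ({class_column!r})")
    rows = []
    for seg, grp in df.groupby("ph_segment_id", sort=True):
        cls = grp[class_column].to_numpy(int)
        signal = grp[cls != PHOTON_NOISE]
        if len(signal) == 0:
            continue
        gz = grp.loc[cls == PHOTON_GROUND, "z"].to_numpy()
        vz = grp.loc[(cls == PHOTON_CANOPY) | (cls == PHOTON_TOC), "z"].to_numpy()
        n_toc = int((cls == PHOTON_TOC).sum())
        row = {"segment_id": seg,
               "x_center": float(signal["x"].mean()),
               "y_center": float(signal["y"].mean()),
               "n_ground": len(gz), "n_canopy": int((cls == PHOTON_CANOPY).sum()),
               "n_toc": n_toc}
        h_te = float(np.mean(gz)) if len(gz) else float("nan")
        row["h_te"] = h_te
        if len(gz) and len(vz) and n_toc:
            rel = vz - h_te
            for j in rh_levels:
                row[f"rh{j}"] = rh_percentile(rel, j)
        else:
            for j in rh_levels:
                row[f"rh{j}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
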