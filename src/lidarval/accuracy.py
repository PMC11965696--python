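"""Accuracy assessment: R^2/RMSE, slope classification, stratified reports,
and the end-to-end validation experiment (footprint scale vs unified 30 m
scale, stratified by slope class).

R^2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2);
RMSE = sqrt(mean((y - yhat)^2)).

Slope classes (degrees, left-closed): Flat [0, 5), Gentle [5, 15),
Moderate [15, 25), Steep [25, 35), ExtremelySteep [35, 45),
Dangerous [45, inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import (QualityFilterSpec, buffer_mean_slope, canopy_rh,
                         filter_footprints, make_buffer,
                         mean_ground_elevation, rh_percentile, track_azimuth)
from .photons import (DEFAULT_MIN_GROUND_PHOTONS, grid_photon_products,
                      lattice_indices, link_atl08_to_atl03, segment_products)
from .raster import Raster
from .types import PhotonTable

__all__ = [
    "SLOPE_CLASSES", "AccuracyReport",
    "rmse", "r_squared", "compute_slope", "classify_slope",
    "stratified_accuracy", "aggregate_reference_grid",
    "run_validation_experiment",
]

#: (label, lower bound inclusive, upper bound exclusive), degrees
SLOPE_CLASSES = (
    ("Flat", 0.0, 5.0),
    ("Gentle", 5.0, 15.0),
    ("Moderate", 15.0, 25.0),
    ("Steep", 25.0, 35.0),
    ("ExtremelySteep", 35.0, 45.0),
    ("Dangerous", 45.0, math.inf),
)

MIN_STRATUM_N = 2  # below this, a stratum reports n only


def rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if len(y) < 2:
        raise ValueError("R^2 needs at least two samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: reference has zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def compute_slope(dem: Raster) -> Raster:
    """Slope in degrees from a 3x3 Horn finite-difference gradient.

    Border cells are flagged NaN (no full 3x3 neighborhood).
    """
    z = dem.data
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope needs at least a 3x3 raster")
    c = dem.cell_size
    # neighbors: rows increase southward, cols increase eastward
    zi = z[1:-1, 1:-1]  # noqa: F841  (alignment reference)
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * c)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * c)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out = np.full_like(z, np.nan)
    out[1:-1, 1:-1] = slope
    return Raster(out, origin=dem.origin, cell_size=dem.cell_size)


def classify_slope(mean_slope_deg: float) -> str:
    """Slope-class label; intervals are left-closed, partitioning [0, inf)."""
    s = float(mean_slope_deg)
    if not np.isfinite(s) or s < 0:
        raise ValueError(f"slope must be finite and nonnegative, got {s}")
    for label, lo, hi in SLOPE_CLASSES:
        if lo <= s < hi:
            return label
    raise AssertionError("unreachable: classes partition [0, inf)")


def stratified_accuracy(pairs: pd.DataFrame,
                        strata=SLOPE_CLASSES) -> pd.DataFrame:
    """Per-slope-class and pooled metrics from (reference, estimate, slope)
    triples. Strata with fewer than two pairs report n only; R^2 is
    withheld (NaN) when the stratum's reference values have no variance."""
    cols = ["slope_class", "r2", "rmse", "n"]
    if len(pairs) == 0:
        return pd.DataFrame(columns=cols)
    df = pairs.dropna(subset=["reference", "estimate", "slope"])
    labels = np.array([classify_slope(s) for s in df["slope"]])
    rows = []
    for label, _, _ in strata:
        sub = df[labels == label]
        rows.append(_metric_row(label, sub))
    rows.append(_metric_row("all", df))
    return pd.DataFrame([r for r in rows if r is not None], columns=cols)


def _metric_row(label: str, sub: pd.DataFrame):
    n = len(sub)
    if n == 0:
        return None
    if n < MIN_STRATUM_N:
        return {"slope_class": label, "r2": np.nan, "rmse": np.nan, "n": n}
    y = sub["reference"].to_numpy()
    yhat = sub["estimate"].to_numpy()
    try:
        r2 = r_squared(y, yhat)
    except ValueError:
        r2 = np.nan  # withheld: zero-variance reference
    return {"slope_class": label, "r2": r2, "rmse": rmse(y, yhat), "n": n}


def aggregate_reference_grid(scene, cell_size: float = 30.0,
                             rh_levels=(80, 85, 90, 95, 98, 100),
                             veg_threshold: float = 2.0) -> pd.DataFrame:
    """Reference DEM/CHM/slope aggregated to the unified grid.

    DEM: mean of fine ground-elevation cells per coarse cell. CHM: RH
    percentiles (same sort-and-index rule as the products) over vegetated
    fine cells (CHM > veg_threshold). Slope: mean Horn slope. Keyed by the
    same global lattice indices the photon gridding uses.
    """
    dem, chm = scene.dem, scene.chm
    slope = compute_slope(dem)
    xs = dem.x_centers()
    ys = dem.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    ix, iy = lattice_indices(xx.ravel(), yy.ravel(), cell_size)
    work = pd.DataFrame({
        "ix": ix, "iy": iy,
        "dem": dem.data.ravel(),
        "chm": (chm.data.ravel() if chm is not None else np.nan),
        "slope": slope.data.ravel(),
    })
    rows = []
    for (cix, ciy), grp in work.groupby(["ix", "iy"], sort=True):
        row = {"ix": cix, "iy": ciy,
               "ref_dem": float(grp["dem"].mean()),
               "ref_slope": float(np.nanmean(grp["slope"]))
               if np.isfinite(grp["slope"]).any() else np.nan}
        veg = grp["chm"].to_numpy()
        veg = veg[np.isfinite(veg) & (veg > veg_threshold)]
        for j in rh_levels:
            row[f"ref_rh{j}"] = rh_percentile(veg, j) if len(veg) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AccuracyReport:
    """Result surface of a validation run: one row per
    (product, variable, scale, slope class) with R^2, RMSE, n; the raw
    evaluation pairs and per-stage record counts are kept for scatter
    plots and diagnostics."""

    table: pd.DataFrame
    pairs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def _stratify_into(report_rows, pairs_out, counts, key, product, variable,
                   scale, pairs: pd.DataFrame):
    pairs_out[key] = pairs
    counts[f"{key}_pairs"] = len(pairs)
    strat = stratified_accuracy(pairs)
    for _, r in strat.iterrows():
        report_rows.append({"product": product, "variable": variable,
                            "scale": scale, **r.to_dict()})


def run_validation_experiment(scene, photon_table: PhotonTable | None = None,
                              footprints=None, rh_j: int = 90,
                              cell_size: float = 30.0,
                              min_ground: int = DEFAULT_MIN_GROUND_PHOTONS,
                              veg_threshold: float = 2.0,
                              quality_spec: QualityFilterSpec | None = None) -> AccuracyReport:
    """Full before/after scale-unification validation on one scene.

    Footprint scale: product values per 100 m segment (photon product,
    rectangular track-aligned buffer) or per footprint (waveform product,
    25 m circular buffer) against reference buffer extractions. Unified
    scale: 30 m gridded products against the 30 m aggregated reference.
    All comparisons are stratified by slope class.
    """
    report_rows: list = []
    pairs_out: dict = {}
    counts: dict = {}
    ref_grid = aggregate_reference_grid(scene, cell_size=cell_size,
                                        rh_levels=(rh_j,),
                                        veg_threshold=veg_threshold)
    ref_grid = ref_grid.set_index(["ix", "iy"])
    slope_raster = compute_slope(scene.dem)

    if photon_table is not None:
        if "classification" not in photon_table.photons.columns:
            linked, skipped = link_atl08_to_atl03(
                photon_table.photons, photon_table.records)
            linked.segments = photon_table.segments
            photon_table = linked
            counts["link_skipped"] = len(skipped)
        segs = segment_products(photon_table, rh_levels=(rh_j,))
        counts["segments"] = len(segs)
        azimuth = track_azimuth(
            photon_table.segments[["x_center", "y_center"]].to_numpy())
        dem_rows, chm_rows = [], []
        for _, s in segs.iterrows():
            buf = make_buffer((s["x_center"], s["y_center"]),
                              shape="rectangle", azimuth=azimuth)
            slope = buffer_mean_slope(slope_raster, buf)
            if np.isfinite(s["h_te"]):
                try:
                    ref = mean_ground_elevation(scene.dem, buf)
                    dem_rows.append({"reference": ref, "estimate": s["h_te"],
                                     "slope": slope})
                except ValueError:
                    pass
            if np.isfinite(s.get(f"rh{rh_j}", np.nan)):
                try:
                    ref = canopy_rh(scene.chm, buf, rh_j,
                                    veg_threshold=veg_threshold)
                    chm_rows.append({"reference": ref,
                                     "estimate": s[f"rh{rh_j}"],
                                     "slope": slope})
                except ValueError:
                    counts["icesat2_chm_buffers_dropped"] = \
                        counts.get("icesat2_chm_buffers_dropped", 0) + 1
        _stratify_into(report_rows, pairs_out, counts, "icesat2_dem_footprint",
                       "icesat2", "DEM", "footprint", pd.DataFrame(dem_rows))
        _stratify_into(report_rows, pairs_out, counts, "icesat2_chm_footprint",
                       "icesat2", "CHM", "footprint", pd.DataFrame(chm_rows))

        grid = grid_photon_products(photon_table.photons,
                                    cell_size=cell_size,
                                    min_ground=min_ground,
                                    rh_levels=(rh_j,))
        cells = grid.cells.set_index(["ix", "iy"]) if len(grid.cells) else \
            pd.DataFrame()
        dem_rows, chm_rows = [], []
        for key, cell in cells.iterrows():
            if key not in ref_grid.index:
                continue
            ref = ref_grid.loc[key]
            if cell["valid_dem"] and np.isfinite(ref["ref_dem"]):
                dem_rows.append({"reference": ref["ref_dem"],
                                 "estimate": cell["dem"],
                                 "slope": ref["ref_slope"]})
            if cell["valid_chm"] and np.isfinite(ref[f"ref_rh{rh_j}"]):
                chm_rows.append({"reference": ref[f"ref_rh{rh_j}"],
                                 "estimate": cell[f"rh{rh_j}"],
                                 "slope": ref["ref_slope"]})
        _stratify_into(report_rows, pairs_out, counts, "icesat2_dem_30m",
                       "icesat2", "DEM", "30m", pd.DataFrame(dem_rows))
        _stratify_into(report_rows, pairs_out, counts, "icesat2_chm_30m",
                       "icesat2", "CHM", "30m", pd.DataFrame(chm_rows))

    if footprints is not None:
        counts["footprints_read"] = len(footprints)
        retained, tally = filter_footprints(footprints, quality_spec)
        counts["footprints_retained"] = len(retained)
        counts["footprint_filter_tally"] = tally
        dem_rows, chm_rows = [], []
        fp_cells: dict = {}
        for fp in retained:
            buf = make_buffer((fp.x, fp.y), shape="circle")
            slope = buffer_mean_slope(slope_raster, buf)
            est_rh = fp.rh.get(rh_j, np.nan) if fp.rh else np.nan
            if np.isfinite(fp.elev_lowestmode):
                try:
                    ref = mean_ground_elevation(scene.dem, buf)
                    dem_rows.append({"reference": ref,
                                     "estimate": fp.elev_lowestmode,
                                     "slope": slope})
                except ValueError:
                    pass
            if np.isfinite(est_rh):
                try:
                    ref = canopy_rh(scene.chm, buf, rh_j,
                                    veg_threshold=veg_threshold)
                    chm_rows.append({"reference": ref, "estimate": est_rh,
                                     "slope": slope})
                except ValueError:
                    counts["gedi_chm_buffers_dropped"] = \
                        counts.get("gedi_chm_buffers_dropped", 0) + 1
            ix, iy = lattice_indices(fp.x, fp.y, cell_size)
            fp_cells.setdefault((int(ix), int(iy)), []).append(
                (fp.elev_lowestmode, est_rh))
        _stratify_into(report_rows, pairs_out, counts, "gedi_dem_footprint",
                       "gedi", "DEM", "footprint", pd.DataFrame(dem_rows))
        _stratify_into(report_rows, pairs_out, counts, "gedi_chm_footprint",
                       "gedi", "CHM", "footprint", pd.DataFrame(chm_rows))

        dem_rows, chm_rows = [], []
        for key, vals in sorted(fp_cells.items()):
            if key not in ref_grid.index:
                continue
            ref = ref_grid.loc[key]
            elevs = np.array([v[0] for v in vals])
            rhs = np.array([v[1] for v in vals])
            elevs = elevs[np.isfinite(elevs)]
            rhs = rhs[np.isfinite(rhs)]
            if len(elevs) and np.isfinite(ref["ref_dem"]):
                dem_rows.append({"reference": ref["ref_dem"],
                                 "estimate": float(elevs.mean()),
                                 "slope": ref["ref_slope"]})
            if len(rhs) and np.isfinite(ref[f"ref_rh{rh_j}"]):
                chm_rows.append({"reference": ref[f"ref_rh{rh_j}"],
                                 "estimate": float(rhs.mean()),
                                 "slope": ref["ref_slope"]})
        _stratify_into(report_rows, pairs_out, counts, "gedi_dem_30m",
                       "gedi", "DEM", "30m", pd.DataFrame(dem_rows))
        _stratify_into(report_rows, pairs_out, counts, "gedi_chm_30m",
                       "gedi", "CHM", "30m", pd.DataFrame(chm_rows))

    table = pd.DataFrame(report_rows,
                         columns=["product", "variable", "scale",
                                  "slope_class", "r2", "rmse", "n"])
    return AccuracyReport(table=table, pairs=pairs_out, counts=counts)
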