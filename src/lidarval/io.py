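"""Readers and writers for the formats the pipeline touches.

LAS 1.2 point-format-0 is read and written directly (fixed 227-byte header
plus 20-byte point records); coordinates are stored at millimeter scale,
so round-trips are lossless to format quantization. Photon tables and
footprint records go to flat HDF5 groups named after the products' field
names, and everything tabular round-trips through CSV.
"""

from __future__ import annotations

import json
import logging
import struct

import h5py
import numpy as np
import pandas as pd
import shapely

from .types import FootprintRecord, PhotonTable, PointCloud
from .waveform import Waveform

__all__ = [
    "read_las", "write_las",
    "write_photons_h5", "read_photons_h5",
    "write_footprints_h5", "read_footprints_h5",
    "buffers_to_geojson", "waveform_to_csv", "waveform_from_csv",
]

logger = logging.getLogger(__name__)

_LAS_HEADER_SIZE = 227
_LAS_POINT0 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
])
_LAS_SCALE = 0.001  # mm quantization


def write_las(cloud: PointCloud, path) -> None:
    """Write a point cloud as LAS 1.2, point format 0."""
    n = len(cloud)
    if n:
        offs = (float(cloud.x.min()), float(cloud.y.min()),
                float(cloud.z.min()))
        maxs = (float(cloud.x.max()), float(cloud.y.max()),
                float(cloud.z.max()))
    else:
        offs = maxs = (0.0, 0.0, 0.0)
    pts = np.zeros(n, dtype=_LAS_POINT0)
    if n:
        pts["X"] = np.round((cloud.x - offs[0]) / _LAS_SCALE).astype("<i4")
        pts["Y"] = np.round((cloud.y - offs[1]) / _LAS_SCALE).astype("<i4")
        pts["Z"] = np.round((cloud.z - offs[2]) / _LAS_SCALE).astype("<i4")
        pts["intensity"] = np.clip(np.round(cloud.intensity), 1,
                                   65535).astype("<u2")
        pts["flags"] = 0x09  # single return, first of one
        pts["classification"] = cloud.classification
    header = bytearray(_LAS_HEADER_SIZE)
    struct.pack_into("<4sHHI", header, 0, b"LASF", 0, 0, 0)
    struct.pack_into("<BB", header, 24, 1, 2)                 # version 1.2
    struct.pack_into("<32s", header, 26, b"lidarval")
    struct.pack_into("<32s", header, 58, b"lidarval")
    struct.pack_into("<HH", header, 90, 1, 2000)              # day, year
    struct.pack_into("<HIIBH", header, 94, _LAS_HEADER_SIZE,
                     _LAS_HEADER_SIZE, 0, 0, _LAS_POINT0.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<5I", header, 111, n, 0, 0, 0, 0)
    struct.pack_into("<3d", header, 131, _LAS_SCALE, _LAS_SCALE, _LAS_SCALE)
    struct.pack_into("<3d", header, 155, *offs)
    struct.pack_into("<6d", header, 179, maxs[0], offs[0], maxs[1],
                     offs[1], maxs[2], offs[2])
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(pts.tobytes())


def read_las(path) -> PointCloud:
    """Read a LAS 1.2 point-format-0 file written by :func:`write_las`
    (or any conforming producer)."""
    with open(path, "rb") as fh:
        header = fh.read(_LAS_HEADER_SIZE)
        if header[:4] != b"LASF":
            raise ValueError(f"{path}: not a LAS file (bad signature)")
        major, minor = struct.unpack_from("<BB", header, 24)
        if (major, minor) != (1, 2):
            raise ValueError(f"{path}: unsupported LAS version "
                             f"{major}.{minor} (only 1.2 is supported)")
        (hsize, offset_to_points, _nvlr, fmt,
         rec_len) = struct.unpack_from("<HIIBH", header, 94)
        if fmt != 0 or rec_len != _LAS_POINT0.itemsize:
            raise ValueError(f"{path}: unsupported point format {fmt} "
                             f"(record length {rec_len})")
        n = struct.unpack_from("<I", header, 107)[0]
        sx, sy, sz = struct.unpack_from("<3d", header, 131)
        ox, oy, oz = struct.unpack_from("<3d", header, 155)
        fh.seek(offset_to_points)
        pts = np.frombuffer(fh.read(n * rec_len), dtype=_LAS_POINT0, count=n)
    if n == 0:
        return PointCloud(np.empty(0), np.empty(0), np.empty(0),
                          np.empty(0), np.empty(0, dtype=np.uint8))
    return PointCloud(pts["X"] * sx + ox, pts["Y"] * sy + oy,
                      pts["Z"] * sz + oz,
                      np.maximum(pts["intensity"].astype(float), 1.0),
                      pts["classification"])


# ---------------------------------------------------------------------------
# HDF5: photon tables and footprint records in flat groups

_REQUIRED_PHOTON = ("x", "y", "z")
_REQUIRED_LINKAGE = ("ph_segment_id", "ph_index_beg", "classed_pc_indx",
                     "classification")


def write_photons_h5(table: PhotonTable, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photons")
        for col in table.photons.columns:
            g.create_dataset(col, data=table.photons[col].to_numpy())
        g = f.create_group("records")
        for col in table.records.columns:
            g.create_dataset(col, data=table.records[col].to_numpy())
        if len(table.segments):
            g = f.create_group("segments")
            for col in table.segments.columns:
                g.create_dataset(col, data=table.segments[col].to_numpy())


def read_photons_h5(path) -> PhotonTable:
    """Read a photon table; hard error on a missing required linkage field,
    logged note on unknown extras."""
    with h5py.File(path, "r") as f:
        for group, required in (("photons", _REQUIRED_PHOTON),
                                ("records", _REQUIRED_LINKAGE)):
            if group not in f:
                raise ValueError(f"{path}: missing group '/{group}'")
            for name in required:
                if name not in f[group]:
                    raise ValueError(f"{path}: missing required field "
                                     f"'/{group}/{name}'")
        photons = pd.DataFrame({k: f["photons"][k][()]
                                for k in f["photons"]})
        records = pd.DataFrame({k: f["records"][k][()]
                                for k in f["records"]})
        segments = (pd.DataFrame({k: f["segments"][k][()]
                                  for k in f["segments"]})
                    if "segments" in f else pd.DataFrame())
    if "photon_index" not in photons.columns:
        logger.info("%s: no photon_index field; assigning 1..n", path)
        photons["photon_index"] = np.arange(1, len(photons) + 1)
    known = set(_REQUIRED_PHOTON) | {"photon_index", "x_true", "y_true", "t",
                                     "ph_segment_id", "truth_class",
                                     "classification"}
    extras = set(photons.columns) - known
    if extras:
        logger.info("%s: ignoring unknown photon fields %s", path,
                    sorted(extras))
    return PhotonTable(photons=photons, records=records, segments=segments)


def write_footprints_h5(footprints: list[FootprintRecord], path) -> None:
    fps = footprints
    rh_levels = sorted(fps[0].rh.keys()) if fps and fps[0].rh else []
    with h5py.File(path, "w") as f:
        g = f.create_group("footprints")
        g.attrs["rh_levels"] = rh_levels
        for name in ("footprint_id", "x", "y", "x_true", "y_true",
                     "elev_lowestmode", "sensitivity", "degrade_flag",
                     "quality_flag", "rx_assess_flag"):
            g.create_dataset(name, data=np.array(
                [getattr(fp, name) for fp in fps]))
        if rh_levels:
            g.create_dataset("rh", data=np.array(
                [[fp.rh.get(j, np.nan) for j in rh_levels] for fp in fps]))
        w = f.create_group("waveforms")
        for fp in fps:
            if fp.waveform is None:
                continue
            d = w.create_group(str(fp.footprint_id))
            d.create_dataset("rxwaveform", data=fp.waveform.wv)
            d.attrs["z_first_bin"] = fp.waveform.z_grid[-1]
            d.attrs["z_last_bin"] = fp.waveform.z_grid[0]
            d.attrs["bin_size"] = fp.waveform.bin_size
            d.attrs["sigma_p"] = fp.waveform.sigma_p


def read_footprints_h5(path) -> list[FootprintRecord]:
    with h5py.File(path, "r") as f:
        if "footprints" not in f:
            raise ValueError(f"{path}: missing group '/footprints'")
        g = f["footprints"]
        for name in ("x", "y", "elev_lowestmode"):
            if name not in g:
                raise ValueError(f"{path}: missing required field "
                                 f"'/footprints/{name}'")
        n = len(g["x"])
        rh_levels = [int(j) for j in g.attrs.get("rh_levels", [])]
        rh = g["rh"][()] if "rh" in g else np.full((n, 0), np.nan)
        cols = {}
        for name in ("footprint_id", "x", "y", "x_true", "y_true",
                     "elev_lowestmode", "sensitivity", "degrade_flag",
                     "quality_flag", "rx_assess_flag"):
            cols[name] = (g[name][()] if name in g
                          else np.full(n, np.nan))
        out = []
        for i in range(n):
            fid = int(cols["footprint_id"][i]) if np.isfinite(
                cols["footprint_id"][i]) else i + 1
            wf = None
            wname = str(fid)
            if "waveforms" in f and wname in f["waveforms"]:
                d = f["waveforms"][wname]
                wv = d["rxwaveform"][()]
                z_lo = float(d.attrs["z_last_bin"])
                bs = float(d.attrs["bin_size"])
                wf = Waveform(z_grid=z_lo + bs * np.arange(len(wv)), wv=wv,
                              bin_size=bs,
                              sigma_p=float(d.attrs.get("sigma_p", 1.0)))
            out.append(FootprintRecord(
                footprint_id=fid, x=float(cols["x"][i]),
                y=float(cols["y"][i]),
                x_true=float(cols["x_true"][i]),
                y_true=float(cols["y_true"][i]),
                elev_lowestmode=float(cols["elev_lowestmode"][i]),
                rh={j: float(rh[i, k]) for k, j in enumerate(rh_levels)},
                sensitivity=float(cols["sensitivity"][i]),
                degrade_flag=int(cols["degrade_flag"][i]),
                quality_flag=int(cols["quality_flag"][i]),
                rx_assess_flag=int(cols["rx_assess_flag"][i]),
                waveform=wf))
    return out


# ---------------------------------------------------------------------------

def buffers_to_geojson(buffers, path) -> None:
    """Export buffer zones as a GeoJSON FeatureCollection for inspection."""
    features = []
    for k, buf in enumerate(buffers):
        features.append({
            "type": "Feature",
            "properties": {"id": k, "shape": buf.shape},
            "geometry": json.loads(shapely.to_geojson(buf.polygon)),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def waveform_to_csv(wf: Waveform, path) -> None:
    pd.DataFrame({"z": wf.z_grid, "intensity": wf.wv}).to_csv(path,
                                                              index=False)


def waveform_from_csv(path, bin_size: float | None = None,
                      sigma_p: float = 1.0) -> Waveform:
    df = pd.read_csv(path)
    z = df["z"].to_numpy()
    if bin_size is None:
        bin_size = float(z[1] - z[0]) if len(z) > 1 else 1.0
    return Waveform(z_grid=z, wv=df["intensity"].to_numpy(),
                    bin_size=bin_size, sigma_p=sigma_p)
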