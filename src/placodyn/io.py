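"""File I/O: OME-TIFF movies, CSV tables, YAML config, JSON summaries."""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import SyntheticMovie

__all__ = [
    "write_ome_tiff",
    "read_ome_tiff",
    "write_surface_tiff",
    "write_tracks_csv",
    "load_config",
    "write_summary_json",
]


def write_ome_tiff(movie: SyntheticMovie, path) -> None:
    """Write a movie as 5D OME-TIFF (TZCYX) with physical calibration."""
    tifffile.imwrite(
        str(path),
        movie.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TZCYX",
            "Channel": {"Name": list(movie.channel_roles)},
            "PhysicalSizeX": movie.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": movie.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": movie.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": movie.frame_interval_s,
            "TimeIncrementUnit": "s",
        },
    )


def read_ome_tiff(path) -> SyntheticMovie:
    """Read a 5D OME-TIFF written by :func:`write_ome_tiff` (truth-free)."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata
    px, pz, dt = 0.25, 1.0, 20.0
    roles = ("membrane", "myosin")
    if ome:
        import re

        m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', ome)
        if m:
            px = float(m.group(1))
        m = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', ome)
        if m:
            pz = float(m.group(1))
        m = re.search(r'TimeIncrement="([\d.eE+-]+)"', ome)
        if m:
            dt = float(m.group(1))
        names = re.findall(r'Channel[^>]*Name="([^"]+)"', ome)
        if len(names) == data.shape[2] if data.ndim == 5 else 0:
            roles = tuple(names)
    if data.ndim == 4:  # single frame stored without T axis
        data = data[None]
    return SyntheticMovie(
        data=np.asarray(data, dtype=np.float32),
        channel_roles=roles,
        pixel_size_um=px,
        z_step_um=pz,
        frame_interval_s=dt,
    )


def write_surface_tiff(surface, path) -> None:
    """Surface height field as a 32-bit float TIFF in μm."""
    tifffile.imwrite(str(path), surface.height_um.astype(np.float32))


_TRACK_COLUMNS = [
    "cell_id", "frame", "t_s", "centroid_x_um", "centroid_y_um",
    "area_um2", "radius_um", "edge_flag", "valid_flag", "placode_flag",
]


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    cols = [c for c in _TRACK_COLUMNS if c in tracks.columns]
    extra = [c for c in tracks.columns if c not in cols]
    tracks[cols + extra].to_csv(path, index=False)


def load_config(path) -> dict:
    """Flat keyed YAML config, namespaced by module (e.g. fluctuation.threshold_myosin)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg


def write_summary_json(summary: dict, path, version: str = "1") -> None:
    out = {"schema_version": version, **summary}
    pathlib.Path(path).write_text(json.dumps(out, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
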