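"""Per-cell geometry, neighbor dispersion, pit-centered coordinates,
radial profiles and area-change rates.

The dispersion statistic D_i — the mean absolute apical-area difference
between a cell and its edge-sharing neighbors — quantifies how spatially
clustered constriction is: ordered, graded constriction gives low D near the
pit, scattered constriction gives uniformly high D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .segmentation import label_adjacency

__all__ = [
    "measure_geometry",
    "neighbor_dispersion",
    "PlacodeFrameGeometry",
    "assign_placode_coordinates",
    "radial_profile",
    "area_change_rate",
]


def measure_geometry(polygon, radius_mode: str = "equivalent_circle") -> dict:
    """Area (μm², shoelace), centroid and cell radius of a simple polygon.

    ``radius_mode`` selects the radius convention: ``equivalent_circle``
    (sqrt(area/π), default) or ``centroid_vertex_mean`` (mean centroid-to-
    vertex distance).
    """
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon))
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    area = poly.area
    cx, cy = poly.centroid.x, poly.centroid.y
    if radius_mode == "equivalent_circle":
        radius = float(np.sqrt(area / np.pi))
    elif radius_mode == "centroid_vertex_mean":
        coords = np.asarray(poly.exterior.coords)[:-1]
        radius = float(np.hypot(coords[:, 0] - cx, coords[:, 1] - cy).mean())
    else:
        raise ValueError(f"unknown radius_mode {radius_mode!r}")
    return {"area_um2": float(area), "radius_um": radius, "centroid": (cx, cy)}


def neighbor_dispersion(labels: np.ndarray, areas: dict) -> dict:
    """Per-cell mean |A_i − A_j| over edge-sharing neighbors j.

    ``areas`` maps label -> apical area (μm²).  Cells without neighbors are
    omitted from the result (their dispersion is undefined).
    """
    nbrs: dict = {}
    for i, j in label_adjacency(labels):
        if i in areas and j in areas:
            nbrs.setdefault(i, []).append(j)
            nbrs.setdefault(j, []).append(i)
    return {
        i: float(np.mean([abs(areas[i] - areas[j]) for j in js]))
        for i, js in nbrs.items()
    }


@dataclass
class PlacodeFrameGeometry:
    """Pit-centered coordinate frame: origin at the pit, anterior distance
    increasing to the left (−x) and ventral distance down (−y), following
    the display convention of placode images."""

    pit_center: np.ndarray
    anterior_axis: np.ndarray = None
    ventral_axis: np.ndarray = None

    def __post_init__(self):
        self.pit_center = np.asarray(self.pit_center, dtype=float)
        if self.anterior_axis is None:
            self.anterior_axis = np.array([-1.0, 0.0])
        if self.ventral_axis is None:
            self.ventral_axis = np.array([0.0, -1.0])


def assign_placode_coordinates(
    tracks: pd.DataFrame,
    pit_center,
    frame_geometry: PlacodeFrameGeometry | None = None,
) -> pd.DataFrame:
    """Add pit-centered coordinates to a tracks table.

    Adds ``r_um`` (Euclidean centroid distance to the pit), ``theta_rad``,
    ``anterior_um`` and ``ventral_um`` columns.
    """
    if pit_center is None:
        raise ValueError("pit_center is required")
    fg = frame_geometry or PlacodeFrameGeometry(pit_center)
    df = tracks.copy()
    dx = df["centroid_x_um"].to_numpy() - fg.pit_center[0]
    dy = df["centroid_y_um"].to_numpy() - fg.pit_center[1]
    df["r_um"] = np.hypot(dx, dy)
    df["theta_rad"] = np.arctan2(dy, dx)
    d = np.stack([dx, dy], axis=1)
    df["anterior_um"] = d @ fg.anterior_axis
    df["ventral_um"] = d @ fg.ventral_axis
    return df


def radial_profile(
    values: np.ndarray,
    r_um: np.ndarray,
    bin_width_um: float = 5.0,
    r_max_um: float | None = None,
) -> pd.DataFrame:
    """Mean ± 95% CI of pooled per-instance values in half-open radial bins.

    The CI is the normal approximation mean ± 1.96·SEM over pooled cell
    instances.  Empty bins are reported with n = 0 and NaN mean; the bin
    counts always sum to the number of finite input values.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    r = np.asarray(r_um, dtype=float)
    if len(values) != len(r) or len(values) < 1:
        raise ValueError("values and radii must be equal-length, non-empty")
    ok = np.isfinite(values) & np.isfinite(r)
    values, r = values[ok], r[ok]
    if r_max_um is None:
        r_max_um = r.max() if len(r) else bin_width_um
    n_bins = max(int(np.ceil((r_max_um + 1e-9) / bin_width_um)), 1)
    edges = np.arange(n_bins + 1) * bin_width_um
    idx = np.clip(np.floor(r / bin_width_um).astype(int), 0, n_bins - 1)

    rows = []
    for b in range(n_bins):
        v = values[idx == b]
        n = len(v)
        if n:
            m = v.mean()
            sem = v.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            rows.append((edges[b], edges[b + 1], m, m - 1.96 * sem, m + 1.96 * sem, n))
        else:
            rows.append((edges[b], edges[b + 1], np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "mean", "ci_lo", "ci_hi", "n"]
    )


def area_change_rate(
    times_s: np.ndarray,
    areas_um2: np.ndarray,
    window_s: float = 60.0,
) -> pd.DataFrame:
    """Instantaneous area-change rates from a centered least-squares window.

    For each instance, dA/dt (μm²/min) and d(lnA)/dt (min⁻¹) are the slopes
    of A(t) and ln A(t) over samples within ±window/2 of the instance
    (negative = constriction).  Instances whose window holds < 3 samples get
    NaN.
    """
    t = np.asarray(times_s, dtype=float)
    a = np.asarray(areas_um2, dtype=float)
    if len(t) != len(a):
        raise ValueError("times and areas must be equal length")
    if len(t) >= 2:
        dt = np.median(np.diff(t))
        if window_s < 2 * dt:
            raise ValueError("window must span at least two frame intervals")
    tmin = t / 60.0
    la = np.log(np.clip(a, 1e-12, None))
    half = window_s / 2.0 / 60.0
    dadt = np.full(len(t), np.nan)
    dlna = np.full(len(t), np.nan)
    for i in range(len(t)):
        m = np.abs(tmin - tmin[i]) <= half + 1e-12
        if m.sum() < 3:
            continue
        x = tmin[m] - tmin[m].mean()
        denom = (x**2).sum()
        if denom <= 0:
            continue
        dadt[i] = (x * (a[m] - a[m].mean())).sum() / denom
        dlna[i] = (x * (la[m] - la[m].mean())).sum() / denom
    return pd.DataFrame({"dA_dt_um2_min": dadt, "dlnA_dt_min": dlna})
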