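"""Curved-surface ("blanket") extraction and quasi-2D projection.

A confocal stack through a curved epithelium has the apical cortical signal
at a different depth in every column.  ``fit_blanket`` drapes a smooth,
contiguous height field over the cortical (membrane) signal;
``project_layer`` then extracts a quasi-2D image as the maximum-intensity
projection of a thin layer of tissue below that surface, which is what the
segmentation stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, grey_erosion, median_filter, zoom

logger = logging.getLogger(__name__)

__all__ = ["SurfaceMap", "ProjectedFrame", "fit_blanket", "project_layer"]


@dataclass
class SurfaceMap:
    """Per-(y, x) height of the apical surface, μm from the first slice."""

    height_um: np.ndarray
    z_step_um: float
    pixel_size_um: float
    smoothness_bound: float  # maximum |∇height|, μm per μm

    @property
    def height_slices(self) -> np.ndarray:
        return self.height_um / self.z_step_um

    def max_gradient(self) -> float:
        gy, gx = np.gradient(self.height_um, self.pixel_size_um)
        return float(np.hypot(gy, gx).max()) if self.height_um.size > 1 else 0.0


@dataclass
class ProjectedFrame:
    """Quasi-2D per-channel images plus projection provenance."""

    channels: dict              # role -> 2D array
    thickness_um: float
    surface: SurfaceMap

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


def fit_blanket(
    zstack: np.ndarray,
    z_step_um: float = 1.0,
    pixel_size_um: float = 0.25,
    smoothness_bound: float = 1.0,
    block_um: float = 2.0,
) -> SurfaceMap:
    """Fit a contiguous smooth surface over the cortical signal of a z-stack.

    The column score is the Gaussian-smoothed intensity; the height is the
    per-column score argmax computed on a laterally block-averaged grid,
    regularized by median + Gaussian filtering, bilinearly upsampled, and
    finally projected onto the Lipschitz cone |∇h| ≤ smoothness_bound.
    ``smoothness_bound = 0`` degenerates to a flat plane at the globally
    best slice.

    Parameters
    ----------
    zstack : (Z, Y, X) intensity array of the channel carrying the cortical
        signal (the membrane channel by convention).
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3:
        raise ValueError("zstack must be 3D (z, y, x)")
    nz, ny, nx = zstack.shape
    if nz < 3:
        if nz == 1:
            return SurfaceMap(
                np.zeros((ny, nx)), z_step_um, pixel_size_um, smoothness_bound
            )
        raise ValueError("zstack must have at least 3 slices")
    if not np.any(zstack > 0):
        raise ValueError("no cortical signal: the stack is identically zero")
    if smoothness_bound < 0:
        raise ValueError("smoothness_bound must be >= 0")

    score = gaussian_filter(zstack, (0.5, 1.0 / pixel_size_um, 1.0 / pixel_size_um))

    if smoothness_bound == 0:
        k = int(np.argmax(score.sum(axis=(1, 2))))
        return SurfaceMap(
            np.full((ny, nx), k * z_step_um), z_step_um, pixel_size_um, 0.0
        )

    # block-average laterally so single-pixel outliers cannot pull the fit
    b = max(int(round(block_um / pixel_size_um)), 1)
    pady, padx = (-ny) % b, (-nx) % b
    sc = np.pad(score, ((0, 0), (0, pady), (0, padx)), mode="edge")
    cy, cx = sc.shape[1] // b, sc.shape[2] // b
    coarse = sc.reshape(nz, cy, b, cx, b).mean(axis=(2, 4))

    hc = np.argmax(coarse, axis=0).astype(float)
    if min(cy, cx) >= 3:
        hc = median_filter(hc, size=3, mode="nearest")
        hc = gaussian_filter(hc, 1.0, mode="nearest")

    h = zoom(hc, (ny + pady) / cy, order=1, mode="nearest")[:ny, :nx] * z_step_um

    # Lipschitz projection (lower envelope): h <= erosion(h) + allowed step
    step = smoothness_bound * pixel_size_um
    footprint = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    for _ in range(64):
        limit = grey_erosion(h, footprint=footprint, mode="nearest") + step
        nh = np.minimum(h, limit)
        if np.allclose(nh, h, atol=1e-12):
            break
        h = nh

    h = np.clip(h, 0.0, (nz - 1) * z_step_um)
    return SurfaceMap(h, z_step_um, pixel_size_um, smoothness_bound)


def project_layer(
    zstack: np.ndarray,
    surface: SurfaceMap,
    thickness_um: float = 1.0,
) -> np.ndarray:
    """Maximum-intensity projection of the layer below the fitted surface.

    For each (y, x) the projection covers z ∈ [height, height + thickness],
    sampled at slice resolution with inclusive endpoints after rounding to
    the nearer slice (so a 1-μm layer at a 1-μm z-step spans exactly two
    slices).  Columns where the slab would leave the stack are clamped, with
    a warning logged.
    """
    zstack = np.asarray(zstack, dtype=float)
    if thickness_um <= 0:
        raise ValueError("thickness must be > 0")
    nz = zstack.shape[0]
    zlo = np.round(surface.height_slices).astype(int)
    zhi = np.round((surface.height_um + thickness_um) / surface.z_step_um).astype(int)
    if np.any(zhi > nz - 1):
        logger.warning(
            "projection slab clamped to the stack depth for %d of %d columns",
            int(np.sum(zhi > nz - 1)),
            zhi.size,
        )
    zlo = np.clip(zlo, 0, nz - 1)
    zhi = np.clip(zhi, 0, nz - 1)

    out = np.full(zstack.shape[1:], -np.inf)
    for z in range(nz):
        inside = (zlo <= z) & (z <= zhi)
        if inside.any():
            out = np.where(inside, np.maximum(out, zstack[z]), out)
    return np.where(np.isfinite(out), out, 0.0)


def project_movie_frame(movie, frame: int, thickness_um: float = 1.0,
                        smoothness_bound: float = 1.0) -> ProjectedFrame:
    """Fit the blanket on the membrane channel of one movie frame and project
    every channel through it."""
    mem = movie.zstack(frame, "membrane")
    surf = fit_blanket(
        mem,
        z_step_um=movie.z_step_um,
        pixel_size_um=movie.pixel_size_um,
        smoothness_bound=smoothness_bound,
    )
    channels = {
        role: project_layer(movie.zstack(frame, role), surf, thickness_um)
        for role in movie.channel_roles
    }
    return ProjectedFrame(channels=channels, thickness_um=thickness_um, surface=surf)
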