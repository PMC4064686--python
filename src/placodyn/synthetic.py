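"""Ground-truthed synthetic placode movies.

This module fabricates the raw data the rest of the package analyses: a
field of polygonal epithelial cells on a gently curved apical surface, each
cell carrying a pulsatile medial myosin signal and an apical area that
constricts in a lagged, ratcheted response to that signal.  Every generated
quantity is retained as ground truth so the measurement pipeline can be
verified end to end without any real microscopy data.

The geometry is a Voronoi tessellation of a jittered hexagonal lattice; the
oscillator is a raised cosine; areas are realized on the tiling by a
conforming vertex relaxation that moves shared vertices consistently, so the
cell polygons always tile the rectangular domain exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

__all__ = [
    "EpitheliumGeometry",
    "OscillationParams",
    "DynamicsGroundTruth",
    "RenderOptics",
    "SyntheticMovie",
    "generate_epithelium",
    "simulate_dynamics",
    "render_movie",
    "make_fixed_placode",
    "dome_height_field",
    "default_scene",
    "rasterize_cells",
    "raised_cosine",
]

_VERTEX_DECIMALS = 9


# ---------------------------------------------------------------------------
# geometry container
# ---------------------------------------------------------------------------

@dataclass
class EpitheliumGeometry:
    """A conforming polygonal tiling of a rectangular domain.

    vertices : (n_vertices, 2) float array, μm.  Shared between cells.
    cells : list of integer index arrays, one per cell, CCW order.
    adjacency : symmetric neighbor graph; an edge means the two cells share
        a boundary segment of positive length.
    pit_center : (2,) invagination-pit position, μm.
    domain : (width, height) of the rectangle with origin (0, 0), μm.
    placode_ids : cell indices flagged as placodal (inside the placode
        ellipse); the rest emulate surrounding epidermis.
    """

    vertices: np.ndarray
    cells: list
    adjacency: nx.Graph
    pit_center: np.ndarray
    domain: tuple
    placode_ids: frozenset
    placode_center: np.ndarray = None
    placode_semiaxes: tuple = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def polygon(self, i: int, vertices: np.ndarray | None = None) -> Polygon:
        v = self.vertices if vertices is None else vertices
        return Polygon(v[self.cells[i]])

    def cell_coords(self, i: int, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        return v[self.cells[i]]

    def areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        return np.array([_shoelace_area(v[c]) for c in self.cells])

    def centroids(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        return np.array([_polygon_centroid(v[c]) for c in self.cells])

    def boundary_vertex_mask(self, tol: float = 1e-9) -> np.ndarray:
        w, h = self.domain
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        on_x = (np.abs(x) < tol) | (np.abs(x - w) < tol)
        on_y = (np.abs(y) < tol) | (np.abs(y - h) < tol)
        return on_x | on_y

    def radial_distances(self, vertices: np.ndarray | None = None) -> np.ndarray:
        c = self.centroids(vertices)
        return np.hypot(*(c - self.pit_center).T)


def _shoelace_area(coords: np.ndarray) -> float:
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(coords: np.ndarray) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return coords.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


# ---------------------------------------------------------------------------
# epithelium generation
# ---------------------------------------------------------------------------

def generate_epithelium(
    n_cells: int,
    domain: tuple = (80.0, 80.0),
    jitter: float = 0.35,
    seed: int = 0,
    placode_center: tuple | None = None,
    placode_semiaxes: tuple | None = None,
    pit_center: tuple | None = None,
) -> EpitheliumGeometry:
    """Voronoi tessellation of a jittered hexagonal lattice, clipped to ``domain``.

    The tiling covers the domain exactly (cells on the rim are clipped by the
    rectangle), so cell areas always sum to the domain area.  Cells whose
    generating site falls inside the placode ellipse are flagged placodal.

    Parameters
    ----------
    n_cells : number of cells (≥ 1).
    domain : (width, height) μm; must be positive.
    jitter : site displacement as a fraction of the lattice pitch, in [0, 0.5].
    seed : RNG seed; output is a pure function of the inputs and the seed.
    """
    w, h = float(domain[0]), float(domain[1])
    if w <= 0 or h <= 0:
        raise ValueError("domain must have positive width and height")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 <= jitter <= 0.5):
        raise ValueError("jitter must be in [0, 0.5]")

    # hexagonal lattice pitch for n_cells hexagons of area w*h/n_cells
    pitch = np.sqrt(2.0 * w * h / (np.sqrt(3.0) * n_cells))
    if pitch < 1.0 and n_cells > 1:
        raise ValueError(
            f"domain {w}x{h} um cannot hold {n_cells} cells at >= 1 um pitch"
        )

    placode_center = (
        np.array([w / 2.0, h / 2.0])
        if placode_center is None
        else np.asarray(placode_center, dtype=float)
    )
    if placode_semiaxes is None:
        placode_semiaxes = (0.44 * min(w, h), 0.44 * min(w, h))
    if pit_center is None:
        pit_center = placode_center + 0.42 * np.asarray(placode_semiaxes)
    pit_center = np.asarray(pit_center, dtype=float)

    if n_cells == 1:
        verts = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])
        g = nx.Graph()
        g.add_node(0)
        return EpitheliumGeometry(
            vertices=verts,
            cells=[np.array([0, 1, 2, 3])],
            adjacency=g,
            pit_center=pit_center,
            domain=(w, h),
            placode_ids=frozenset({0}),
            placode_center=placode_center,
            placode_semiaxes=tuple(placode_semiaxes),
        )

    rng = np.random.default_rng(seed)
    sites = _hex_sites(w, h, pitch, n_cells)
    if jitter > 0:
        sites = sites + rng.uniform(-jitter * pitch, jitter * pitch, size=sites.shape)
        sites[:, 0] = np.clip(sites[:, 0], 1e-6, w - 1e-6)
        sites[:, 1] = np.clip(sites[:, 1], 1e-6, h - 1e-6)

    verts, cells, adjacency = _bounded_voronoi(sites, w, h)

    centroids = np.array([_polygon_centroid(verts[c]) for c in cells])
    dx = (centroids[:, 0] - placode_center[0]) / placode_semiaxes[0]
    dy = (centroids[:, 1] - placode_center[1]) / placode_semiaxes[1]
    placode_ids = frozenset(np.nonzero(dx**2 + dy**2 <= 1.0)[0].tolist())

    return EpitheliumGeometry(
        vertices=verts,
        cells=cells,
        adjacency=adjacency,
        pit_center=pit_center,
        domain=(w, h),
        placode_ids=placode_ids,
        placode_center=placode_center,
        placode_semiaxes=tuple(placode_semiaxes),
    )


def _hex_sites(w: float, h: float, pitch: float, n_cells: int) -> np.ndarray:
    """Hexagonal lattice covering the domain; the n_cells sites nearest the
    domain center are kept (all sites lie inside the domain)."""
    pts = np.empty((0, 2))
    p = pitch
    for _ in range(12):  # shrink until the lattice holds n_cells sites
        dy = p * np.sqrt(3.0) / 2.0
        rows = []
        row = 0
        y = p / 2.0
        while y < h:
            x = p / 2.0 + (p / 2.0 if row % 2 else 0.0)
            while x < w:
                rows.append((x, y))
                x += p
            y += dy
            row += 1
        pts = np.asarray(rows, dtype=float)
        if len(pts) >= n_cells:
            break
        p *= 0.97
    if len(pts) < n_cells or p < 1.0:
        raise ValueError(
            f"domain {w}x{h} um cannot hold {n_cells} cells at >= 1 um pitch"
        )
    center = np.array([w / 2.0, h / 2.0])
    order = np.argsort(((pts - center) ** 2).sum(axis=1), kind="stable")
    return pts[order[:n_cells]]


def _bounded_voronoi(sites: np.ndarray, w: float, h: float):
    """Voronoi diagram clipped to [0,w]x[0,h] via the four-mirror trick.

    Mirror images of every site across each domain edge bound all original
    regions, and place region edges exactly on the rectangle boundary.
    """
    mirrors = [
        sites * [-1, 1],
        sites * [1, -1],
        np.column_stack([2 * w - sites[:, 0], sites[:, 1]]),
        np.column_stack([sites[:, 0], 2 * h - sites[:, 1]]),
    ]
    allpts = np.vstack([sites] + mirrors)
    vor = Voronoi(allpts)

    n = len(sites)
    raw_polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        coords = vor.vertices[region]
        # CCW order around the site
        ang = np.arctan2(coords[:, 1] - sites[i, 1], coords[:, 0] - sites[i, 0])
        coords = coords[np.argsort(ang, kind="stable")]
        raw_polys.append(np.round(coords, _VERTEX_DECIMALS))

    # shared vertex table
    vert_index: dict = {}
    verts: list = []
    cells = []
    for coords in raw_polys:
        idx = []
        for p in coords:
            key = (p[0], p[1])
            j = vert_index.get(key)
            if j is None:
                j = len(verts)
                vert_index[key] = j
                verts.append(p)
            idx.append(j)
        cells.append(np.array(idx, dtype=int))
    verts = np.array(verts)
    # snap boundary vertices exactly onto the rectangle
    verts[:, 0] = np.where(np.abs(verts[:, 0]) < 1e-6, 0.0, verts[:, 0])
    verts[:, 1] = np.where(np.abs(verts[:, 1]) < 1e-6, 0.0, verts[:, 1])
    verts[:, 0] = np.where(np.abs(verts[:, 0] - w) < 1e-6, w, verts[:, 0])
    verts[:, 1] = np.where(np.abs(verts[:, 1] - h) < 1e-6, h, verts[:, 1])

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p < n and q < n and -1 not in rv:
            seg = vor.vertices[rv]
            if np.hypot(*(seg[1] - seg[0])) > 1e-9:
                g.add_edge(int(p), int(q))
    return verts, cells, g


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

@dataclass
class OscillationParams:
    """Parameters of the pulsatile myosin / constriction dynamics.

    period_mean, period_sd : s.  Cell periods are drawn N(mean, sd²); the
        observed cycle-length range of medial myosin pulses in the placode
        (~120-180 s) motivates the defaults.
    myosin_amplitude : grayscale units, trough-to-peak size of the medial
        myosin pulse in the most active (pit-proximal) cells.
    myosin_baseline : grayscale units of non-pulsing placodal medial myosin.
    lag_cycles : fraction of a cycle by which the (inverse-radius) response
        trails myosin; wild-type behavior is about one-eighth of a cycle.
    constriction_gain : μm² of constriction per grayscale-unit·min of myosin
        excess over baseline.
    radial_gradient : dimensionless; fractional reduction of pulse amplitude
        from the pit to the far edge of the placode (activity decreases away
        from the pit).
    ratchet_fraction : fraction of each constriction pulse retained after the
        stabilization phase (0 = purely elastic pulsing, 1 = no recovery).
    """

    period_mean: float = 150.0
    period_sd: float = 15.0
    myosin_amplitude: float = 10.0
    myosin_baseline: float = 20.0
    lag_cycles: float = 0.125
    constriction_gain: float = 0.25
    radial_gradient: float = 0.5
    ratchet_fraction: float = 0.3

    def __post_init__(self):
        if self.period_mean <= 0:
            raise ValueError("period_mean must be > 0")
        if not (0.0 <= self.lag_cycles < 1.0):
            raise ValueError("lag_cycles must be in [0, 1)")
        if not (0.0 <= self.ratchet_fraction <= 1.0):
            raise ValueError("ratchet_fraction must be in [0, 1]")


def raised_cosine(phase: np.ndarray) -> np.ndarray:
    """Smooth single-peaked pulse waveform on [0, 1): 0 at phase 0, 1 at 0.5."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(phase)))


@dataclass
class DynamicsGroundTruth:
    """Per-cell, per-frame generating truth of a synthetic movie.

    ``area`` holds the analytic target areas (which carry the generating lag
    exactly); ``vertices_t`` holds the conforming polygon realization used
    for rendering, whose areas track the targets approximately.
    """

    geometry: EpitheliumGeometry
    times: np.ndarray                 # (T,) s
    myosin: np.ndarray                # (T, C) grayscale, medial mean
    area: np.ndarray                  # (T, C) μm², analytic
    phase: np.ndarray                 # (T, C) in [0, 1), myosin phase
    vertices_t: np.ndarray            # (T, n_vertices, 2) μm
    periods: np.ndarray               # (C,) s
    amplitudes: np.ndarray            # (C,) grayscale
    params: OscillationParams = None
    frame_interval: float = 20.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def radius(self) -> np.ndarray:
        return np.sqrt(self.area / np.pi)

    def polygon_areas(self) -> np.ndarray:
        return np.stack(
            [self.geometry.areas(self.vertices_t[t]) for t in range(self.n_frames)]
        )

    def continuous_traces(self, cell: int, times: np.ndarray):
        """Analytic (myosin, area) traces of one cell at arbitrary times.

        Used by dense-sampling oracles; identical formulas to the sampled
        truth.
        """
        t = np.asarray(times, dtype=float)
        ph = t / self.periods[cell] + self._phase0[cell]
        myo = self.params.myosin_baseline + self.amplitudes[cell] * raised_cosine(ph)
        dA = self._pulse_depth[cell]
        area = (
            self._area0[cell]
            - dA * raised_cosine(ph - self.params.lag_cycles)
            - self.params.ratchet_fraction * dA * (t / self.periods[cell])
        )
        return myo, area

    def to_frame(self):
        """Tidy truth table (cell_id, frame, t_s, area_um2, radius_um,
        myosin_true, phase_true, placode_flag)."""
        import pandas as pd

        T, C = self.myosin.shape
        frames, cells = np.meshgrid(np.arange(T), np.arange(C), indexing="ij")
        return pd.DataFrame(
            {
                "cell_id": cells.ravel(),
                "frame": frames.ravel(),
                "t_s": np.repeat(self.times, C),
                "area_um2": self.area.ravel(),
                "radius_um": self.radius.ravel(),
                "myosin_true": self.myosin.ravel(),
                "phase_true": self.phase.ravel(),
                "placode_flag": np.isin(
                    cells.ravel(), sorted(self.geometry.placode_ids)
                ),
            }
        )


def simulate_dynamics(
    geom: EpitheliumGeometry,
    params: OscillationParams | None = None,
    frame_interval: float = 20.0,
    duration: float = 900.0,
    seed: int = 0,
    relax_iter: int = 40,
) -> DynamicsGroundTruth:
    """Simulate pulsatile myosin and ratcheted, lagged apical constriction.

    Each placodal cell i oscillates with its own period T_i ~ N(period_mean,
    period_sd²) and a random initial phase.  Its medial myosin is
    ``baseline + a_i·rc(φ_i)`` where rc is a raised cosine and the amplitude
    a_i falls off linearly with radial distance from the pit
    (``radial_gradient``).  The apical area executes, per cycle, a
    constriction pulse of depth ΔA_i = gain·⟨m−b⟩_i·T_i/60 whose waveform is
    the myosin waveform delayed by ``lag_cycles``, of which
    ``ratchet_fraction`` is retained as a linear constriction trend.

    Polygons are re-fit to the target areas each frame by conforming vertex
    relaxation (shared vertices moved consistently; domain-boundary vertices
    stay on the boundary), so the tiling covers the domain at all times.
    """
    params = params or OscillationParams()
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if duration < 2 * params.period_mean:
        raise ValueError("duration must be at least two mean periods")

    rng = np.random.default_rng(seed)
    C = geom.n_cells
    times = np.arange(0.0, duration + 0.5 * frame_interval, frame_interval)
    T = len(times)

    periods = np.maximum(
        rng.normal(params.period_mean, params.period_sd, size=C), 1e-2
    )
    phase0 = rng.uniform(0.0, 1.0, size=C)

    # radial activity scaling, placodal cells only
    r = geom.radial_distances()
    placodal = np.zeros(C, dtype=bool)
    placodal[sorted(geom.placode_ids)] = True
    rmax = r[placodal].max() if placodal.any() else 1.0
    scale = np.clip(1.0 - params.radial_gradient * r / max(rmax, 1e-9), 0.0, None)
    amplitudes = np.where(placodal, params.myosin_amplitude * scale, 0.0)

    area0 = geom.areas()
    # per-cycle pulse depth: gain [μm²/(gs·min)] × mean excess [gs] × T [min]
    pulse_depth = params.constriction_gain * (amplitudes / 2.0) * periods / 60.0

    n_cycles = duration / periods
    min_area = area0 - pulse_depth * (1.0 + params.ratchet_fraction * n_cycles)
    if np.any(min_area <= 0):
        bad = int(np.argmin(min_area))
        raise ValueError(
            "parameters imply non-positive area within the duration "
            f"(cell {bad}: initial {area0[bad]:.2f} um2, "
            f"implied minimum {min_area[bad]:.2f} um2)"
        )

    tt = times[:, None]
    phase = (tt / periods[None, :] + phase0[None, :]) % 1.0
    myosin = params.myosin_baseline + amplitudes[None, :] * raised_cosine(
        tt / periods[None, :] + phase0[None, :]
    )
    area = (
        area0[None, :]
        - pulse_depth[None, :]
        * raised_cosine(tt / periods[None, :] + phase0[None, :] - params.lag_cycles)
        - params.ratchet_fraction * pulse_depth[None, :] * (tt / periods[None, :])
    )

    # conforming polygon realization
    incidence = _vertex_incidence(geom)
    boundary = geom.boundary_vertex_mask()
    verts_t = np.empty((T, len(geom.vertices), 2))
    v = geom.vertices.copy()
    for t in range(T):
        v = _relax_to_areas(geom, v, area[t], incidence, boundary, relax_iter)
        verts_t[t] = v

    truth = DynamicsGroundTruth(
        geometry=geom,
        times=times,
        myosin=myosin,
        area=area,
        phase=phase,
        vertices_t=verts_t,
        periods=periods,
        amplitudes=amplitudes,
        params=params,
        frame_interval=frame_interval,
        seed=seed,
    )
    truth._phase0 = phase0
    truth._area0 = area0
    truth._pulse_depth = pulse_depth
    return truth


class _TilingArrays:
    """Flat-index representation of the tiling for vectorized relaxation."""

    def __init__(self, geom: EpitheliumGeometry):
        self.flat = np.concatenate(geom.cells)
        counts = np.array([len(c) for c in geom.cells])
        self.offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.cell_of = np.repeat(np.arange(geom.n_cells), counts)
        # within-cell next position for the shoelace formula
        nxt = np.arange(len(self.flat)) + 1
        ends = np.cumsum(counts) - 1
        nxt[ends] = self.offsets
        self.next_flat = self.flat[nxt]
        self.n_cells = geom.n_cells
        self.n_verts = len(geom.vertices)
        deg = np.bincount(self.flat, minlength=self.n_verts)
        self.deg = np.maximum(deg, 1).astype(float)

    def areas_centroids(self, v: np.ndarray):
        x, y = v[self.flat, 0], v[self.flat, 1]
        xn, yn = v[self.next_flat, 0], v[self.next_flat, 1]
        cross = x * yn - xn * y
        a2 = np.add.reduceat(cross, self.offsets)
        areas = np.abs(a2) / 2.0
        cx = np.add.reduceat((x + xn) * cross, self.offsets) / (3.0 * np.where(a2 == 0, 1, a2))
        cy = np.add.reduceat((y + yn) * cross, self.offsets) / (3.0 * np.where(a2 == 0, 1, a2))
        return areas, np.column_stack([cx, cy])


def _vertex_incidence(geom: EpitheliumGeometry) -> _TilingArrays:
    return _TilingArrays(geom)


def _relax_to_areas(geom, verts, target_areas, arrays: _TilingArrays,
                    boundary, n_iter):
    """Move shared vertices toward per-cell centroid scalings that realize the
    target areas, averaging the displacements requested by incident cells.

    Targets are generally not exactly feasible on a fixed-topology tiling of a
    fixed domain; the iteration converges to a conforming compromise.
    """
    v = verts.copy()
    for _ in range(n_iter):
        areas, cents = arrays.areas_centroids(v)
        s = np.sqrt(np.clip(target_areas, 1e-6, None) / np.maximum(areas, 1e-9))
        s = np.clip(s, 0.8, 1.25)  # damp extreme per-step scalings
        contrib = (
            cents[arrays.cell_of]
            + s[arrays.cell_of, None] * (v[arrays.flat] - cents[arrays.cell_of])
        )
        acc = np.zeros((arrays.n_verts, 2))
        np.add.at(acc, arrays.flat, contrib)
        newv = acc / arrays.deg[:, None]
        newv[boundary] = v[boundary]
        v = newv
    return v


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderOptics:
    """Imaging model for rendering truth into a two-channel z-stack.

    The surface height field places the signal in z; a Gaussian PSF blurs it;
    scaled-Poisson photon noise plus Gaussian read noise corrupt it.
    ``photon_noise_scale = 0`` and ``psf_sigma_um = 0`` give a clean render.
    """

    pixel_size_um: float = 0.25
    z_step_um: float = 1.0
    n_z: int = 10
    psf_sigma_um: float = 0.3
    psf_sigma_z_um: float = 0.6
    background: float = 3.0
    photon_noise_scale: float = 100.0
    read_noise: float = 0.25
    membrane_intensity: float = 60.0
    junctional_myosin: float = 12.0
    epidermal_myosin: float = 8.0
    medial_band_um: float = 0.5
    flow_blob_fraction: float = 0.2
    flow_blob_sigma_um: float = 0.8
    surface_height: np.ndarray | None = None  # (ny, nx) μm; default: dome


@dataclass
class SyntheticMovie:
    """5D synthetic movie (t, z, channel, y, x) with calibration and truth."""

    data: np.ndarray                      # float32, nonnegative
    channel_roles: tuple = ("membrane", "myosin")
    pixel_size_um: float = 0.25
    z_step_um: float = 1.0
    frame_interval_s: float = 20.0
    surface_truth: np.ndarray = None      # (ny, nx) μm
    truth: DynamicsGroundTruth = None
    optics: RenderOptics = None

    @property
    def n_frames(self):
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def channel(self, role: str) -> int:
        return self.channel_roles.index(role)

    def zstack(self, frame: int, role: str) -> np.ndarray:
        return self.data[frame, :, self.channel(role)]

    def truth_labels(self, frame: int) -> np.ndarray:
        """Rasterized ground-truth cell labels (cell_id + 1; 0 outside)."""
        ny, nx = self.data.shape[-2:]
        return rasterize_cells(
            self.truth.geometry,
            self.truth.vertices_t[frame],
            (ny, nx),
            self.pixel_size_um,
        )

    def placode_pixel_mask(self) -> np.ndarray:
        geom = self.truth.geometry
        ny, nx = self.data.shape[-2:]
        yy, xx = np.mgrid[0:ny, 0:nx]
        x = (xx + 0.5) * self.pixel_size_um
        y = (yy + 0.5) * self.pixel_size_um
        cx, cy = geom.placode_center
        ax, ay = geom.placode_semiaxes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def dome_height_field(
    shape: tuple,
    pixel_size_um: float,
    base_um: float = 2.0,
    amplitude_um: float = 4.0,
    sigma_um: float = 30.0,
    center: tuple | None = None,
) -> np.ndarray:
    """Gently curved apical surface: a Gaussian dome over a flat base."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x = (xx + 0.5) * pixel_size_um
    y = (yy + 0.5) * pixel_size_um
    if center is None:
        center = (nx * pixel_size_um / 2.0, ny * pixel_size_um / 2.0)
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    return base_um + amplitude_um * np.exp(-r2 / (2.0 * sigma_um**2))


def rasterize_cells(
    geom: EpitheliumGeometry,
    vertices: np.ndarray,
    shape: tuple,
    pixel_size_um: float,
) -> np.ndarray:
    """Label image of the tiling; label = cell_id + 1.  Pixel centers at
    (i + 0.5)·pixel_size."""
    from skimage.draw import polygon as draw_polygon

    ny, nx = shape
    labels = np.zeros((ny, nx), dtype=np.int32)
    for ci, cell in enumerate(geom.cells):
        coords = vertices[cell]
        rr, cc = draw_polygon(
            coords[:, 1] / pixel_size_um - 0.5,
            coords[:, 0] / pixel_size_um - 0.5,
            shape=(ny, nx),
        )
        labels[rr, cc] = ci + 1
    return labels


def render_movie(
    truth: DynamicsGroundTruth,
    optics: RenderOptics | None = None,
    seed: int = 0,
) -> SyntheticMovie:
    """Render ground truth into a noisy two-channel confocal-like stack.

    The membrane channel is the cell-boundary skeleton painted in a thin
    shell at the surface height; the myosin channel paints each cell's true
    medial value inside its inwardly-offset polygon (optionally redistributed
    into orbiting "flow" blobs with the mask mean preserved exactly) plus a
    junctional component along boundaries.  Gaussian PSF blur and
    scaled-Poisson + read noise follow.
    """
    from scipy.ndimage import binary_erosion
    from skimage.morphology import disk
    from skimage.segmentation import find_boundaries

    optics = optics or RenderOptics()
    geom = truth.geometry
    p = optics.pixel_size_um
    w, h = geom.domain
    nx = int(round(w / p))
    ny = int(round(h / p))
    nzt = optics.n_z

    if optics.surface_height is None:
        height = dome_height_field((ny, nx), p)
    else:
        height = np.asarray(optics.surface_height, dtype=float)
        if height.shape != (ny, nx):
            raise ValueError("surface_height shape does not match the domain")
    zmax = (nzt - 1) * optics.z_step_um
    if height.min() < 0 or height.max() > zmax:
        raise ValueError(
            f"surface height range [{height.min():.2f}, {height.max():.2f}] um "
            f"leaves the stack z range [0, {zmax:.2f}] um"
        )
    # signal is split between the two nearest slices with linear weights
    # (emulating optical sectioning); an integer-slice surface paints a
    # single slice exactly
    zf = height / optics.z_step_um
    zlo_s = np.clip(np.floor(zf).astype(int), 0, nzt - 1)
    zhi_s = np.clip(zlo_s + 1, 0, nzt - 1)
    w_hi = np.clip(zf - zlo_s, 0.0, 1.0)
    w_lo = 1.0 - w_hi

    rng = np.random.default_rng(seed)
    placodal = np.zeros(geom.n_cells, dtype=bool)
    placodal[sorted(geom.placode_ids)] = True
    band_px = max(int(round(optics.medial_band_um / p)), 1)
    selem = disk(band_px)

    T = truth.n_frames
    data = np.zeros((T, nzt, 2, ny, nx), dtype=np.float32)
    blob_phase0 = rng.uniform(0, 1, size=geom.n_cells)

    for t in range(T):
        labels = rasterize_cells(geom, truth.vertices_t[t], (ny, nx), p)
        boundary = find_boundaries(labels, mode="thick") | (labels == 0)

        mem = np.where(boundary, optics.membrane_intensity, 0.0)

        myo = np.zeros((ny, nx))
        from scipy.ndimage import find_objects

        slices = find_objects(labels)
        for ci in range(geom.n_cells):
            sl = slices[ci] if ci < len(slices) else None
            if sl is None:
                continue
            mask = labels[sl] == ci + 1
            interior = mask & ~boundary[sl]
            medial = binary_erosion(mask, selem) & interior
            mval = truth.myosin[t, ci] if placodal[ci] else optics.epidermal_myosin
            sub = myo[sl]
            junctional = interior & ~medial
            sub[junctional] = optics.junctional_myosin
            npx = medial.sum()
            if npx == 0:
                continue
            # flow blobs carry part of the *pulsatile* pool only, so
            # non-oscillating cells image as a uniform medial sheet
            if placodal[ci] and mval > 0:
                excess = max(mval - truth.params.myosin_baseline, 0.0)
                f = optics.flow_blob_fraction * excess / mval
            else:
                f = 0.0
            if f > 0:
                cy, cx = np.nonzero(medial)
                c0y, c0x = cy.mean(), cx.mean()
                rad = 0.5 * np.sqrt(npx / np.pi)
                th = 2 * np.pi * (
                    blob_phase0[ci] + truth.times[t] / truth.periods[ci]
                )
                by = c0y + rad * np.sin(th)
                bx = c0x + rad * np.cos(th)
                s2 = (optics.flow_blob_sigma_um / p) ** 2
                g = np.exp(-((cy - by) ** 2 + (cx - bx) ** 2) / (2 * s2))
                gsum = g.sum()
                blob = g * (f * mval * npx / gsum) if gsum > 0 else 0.0
                vals = mval * (1.0 - f) + blob
            else:
                vals = np.full(npx, mval)
            sub[medial] = vals
            myo[sl] = sub
        myo[boundary] = optics.junctional_myosin

        for z in range(nzt):
            lo = zlo_s == z
            if lo.any():
                data[t, z, 0][lo] += (w_lo * mem)[lo]
                data[t, z, 1][lo] += (w_lo * myo)[lo]
            hi = (zhi_s == z) & (w_hi > 0)
            if hi.any():
                data[t, z, 0][hi] += (w_hi * mem)[hi]
                data[t, z, 1][hi] += (w_hi * myo)[hi]

        if optics.psf_sigma_um > 0:
            sig = (
                optics.psf_sigma_z_um / optics.z_step_um,
                optics.psf_sigma_um / p,
                optics.psf_sigma_um / p,
            )
            data[t, :, 0] = gaussian_filter(data[t, :, 0], sig)
            data[t, :, 1] = gaussian_filter(data[t, :, 1], sig)

    data += optics.background
    if optics.photon_noise_scale > 0:
        lam = np.clip(data, 0, None).astype(np.float64) * optics.photon_noise_scale
        data = (rng.poisson(lam) / optics.photon_noise_scale).astype(np.float32)
    if optics.read_noise > 0:
        data = data + rng.normal(0.0, optics.read_noise, size=data.shape).astype(
            np.float32
        )
    data = np.clip(data, 0.0, None).astype(np.float32)

    return SyntheticMovie(
        data=data,
        pixel_size_um=p,
        z_step_um=optics.z_step_um,
        frame_interval_s=truth.frame_interval,
        surface_truth=height,
        truth=truth,
        optics=optics,
    )


# ---------------------------------------------------------------------------
# fixed-frame placodes
# ---------------------------------------------------------------------------

def make_fixed_placode(
    pattern: str,
    n_cells: int = 250,
    seed: int = 0,
    domain: tuple = (80.0, 80.0),
    optics: RenderOptics | None = None,
    gradient_noise: float = 0.15,
):
    """Single-frame placode image emulating fixed-embryo area patterns.

    ``wildtype_gradient`` draws per-cell target areas and assigns the small
    ones preferentially near the pit (clustered constriction);
    ``dispersed`` scatters the *same multiset* of areas uniformly over the
    placode, so the two patterns differ only in spatial arrangement.

    Returns (SyntheticMovie with one frame, EpitheliumGeometry, truth table).
    """
    if pattern not in ("wildtype_gradient", "dispersed"):
        raise ValueError("pattern must be 'wildtype_gradient' or 'dispersed'")
    if n_cells < 20:
        raise ValueError("n_cells must be >= 20")

    rng = np.random.default_rng(seed)
    geom = generate_epithelium(n_cells, domain=domain, jitter=0.35, seed=seed)
    area0 = geom.areas()
    placodal = np.array(sorted(geom.placode_ids))
    r = geom.radial_distances()[placodal]

    # one multiset of target areas for both patterns (same seed => identical)
    mean_area = area0[placodal].mean()
    factors = np.sort(rng.uniform(0.35, 1.35, size=len(placodal)))
    target = area0.copy()

    if pattern == "wildtype_gradient":
        # small areas near the pit: rank-match distance to sorted factors,
        # with noise so the correlation is strong but not perfect
        noisy_rank = np.argsort(
            np.argsort(r + gradient_noise * r.std() * rng.normal(size=len(r)),
                       kind="stable"), kind="stable"
        )
        target[placodal] = mean_area * factors[noisy_rank]
    else:
        perm = rng.permutation(len(placodal))
        target[placodal] = mean_area * factors[perm]

    incidence = _vertex_incidence(geom)
    boundary = geom.boundary_vertex_mask()
    v = _relax_to_areas(geom, geom.vertices, target, incidence, boundary, 60)

    truth = DynamicsGroundTruth(
        geometry=geom,
        times=np.array([0.0]),
        myosin=np.full((1, geom.n_cells), 20.0),
        area=target[None, :],
        phase=np.zeros((1, geom.n_cells)),
        vertices_t=v[None, :, :],
        periods=np.full(geom.n_cells, 150.0),
        amplitudes=np.zeros(geom.n_cells),
        params=OscillationParams(),
        frame_interval=20.0,
        seed=seed,
    )
    truth._phase0 = np.zeros(geom.n_cells)
    truth._area0 = target
    truth._pulse_depth = np.zeros(geom.n_cells)

    optics = optics or RenderOptics(flow_blob_fraction=0.0)
    movie = render_movie(truth, optics, seed=seed)
    return movie, geom, truth.to_frame()


def truth_subset(truth: DynamicsGroundTruth, frames) -> DynamicsGroundTruth:
    """Restrict a ground truth to a subset of frames (e.g. for rendering a
    single reference frame)."""
    frames = np.atleast_1d(frames)
    sub = DynamicsGroundTruth(
        geometry=truth.geometry,
        times=truth.times[frames],
        myosin=truth.myosin[frames],
        area=truth.area[frames],
        phase=truth.phase[frames],
        vertices_t=truth.vertices_t[frames],
        periods=truth.periods,
        amplitudes=truth.amplitudes,
        params=truth.params,
        frame_interval=truth.frame_interval,
        seed=truth.seed,
    )
    sub._phase0 = truth._phase0
    sub._area0 = truth._area0
    sub._pulse_depth = truth._pulse_depth
    return sub


def default_scene(seed: int = 7, duration: float = 900.0,
                  optics: RenderOptics | None = None) -> SyntheticMovie:
    """The package's reference study scene: an 80×80 μm field of 250 cells
    (~150 placodal), 15 min at 20 s sampling, default oscillation params."""
    geom = generate_epithelium(250, domain=(80.0, 80.0), jitter=0.35, seed=seed)
    truth = simulate_dynamics(geom, OscillationParams(), 20.0, duration, seed=seed)
    return render_movie(truth, optics or RenderOptics(), seed=seed)


def params_to_json(params: OscillationParams, optics: RenderOptics | None = None) -> str:
    d = {"oscillation": dataclasses.asdict(params)}
    if optics is not None:
        od = dataclasses.asdict(optics)
        od.pop("surface_height", None)
        d["optics"] = od
    return json.dumps(d, indent=2)
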