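"""Cell segmentation, frame-to-frame linking and track quality control.

Apical cell outlines are segmented on projected membrane images with a
watershed on a block-adaptively normalized relief ("adaptive watershed"),
cells are linked through time by greedy maximal-overlap matching, and the
resulting tracks are filtered with rules for implausible size, relative
speed to neighbors, area-change rate, field-of-view clipping and short
lineages.  Filtering only flags instances; it never alters geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.spatial import cKDTree

__all__ = [
    "segment_cells",
    "link_frames",
    "build_tracks",
    "label_adjacency",
    "QCRules",
    "qc_filter",
    "apply_label_edits",
]


def segment_cells(
    membrane: np.ndarray,
    pixel_size_um: float = 0.25,
    membrane_smoothing_um: float = 0.4,
    seed_min_distance_um: float = 2.0,
    adaptive_block_um: float = 15.0,
    seed_h_rel: float = 0.15,
) -> np.ndarray:
    """Watershed segmentation of a projected membrane image.

    The image is locally contrast-normalized ((I − μ_block)/σ_block with a
    block of ``adaptive_block_um``), Gaussian-smoothed, and watershed basins
    are grown from the regional minima of the relief (membrane ridges are
    maxima).  Shallow minima are suppressed with an h-minima transform
    (depth ``seed_h_rel``·std of the relief) and seeds closer than
    ``seed_min_distance_um`` are merged, keeping the deeper one.  Boundary
    pixels between basins are labeled 0.

    Because the relief is normalized, the labeling is invariant to positive
    rescaling of the input.
    """
    from skimage.measure import label as cc_label
    from skimage.morphology import local_minima, reconstruction
    from skimage.segmentation import watershed

    img = np.asarray(membrane, dtype=float)
    if img.ndim != 2:
        raise ValueError("membrane image must be 2D")
    if np.ptp(img) == 0:
        raise ValueError("no gradients: the membrane image is constant")

    block = max(int(round(adaptive_block_um / pixel_size_um)), 3)
    mu = uniform_filter(img, block, mode="reflect")
    var = np.clip(uniform_filter(img**2, block, mode="reflect") - mu**2, 0, None)
    sd = np.sqrt(var)
    eps = 1e-9 * np.ptp(img)  # scales with the image => exact scale invariance
    relief = (img - mu) / (sd + eps)

    sigma = membrane_smoothing_um / pixel_size_um
    if sigma > 0:
        relief = gaussian_filter(relief, sigma)

    # suppress minima shallower than h, then find plateau-aware minima
    h = seed_h_rel * relief.std()
    if h > 0:
        filled = reconstruction(relief + h, relief, method="erosion")
    else:
        filled = relief
    minima = local_minima(filled, connectivity=2)
    markers = cc_label(minima, connectivity=2)

    n_seed = markers.max()
    if n_seed == 0:
        raise ValueError("no gradients: no watershed seeds found")

    # enforce the minimum seed separation: greedily keep deeper seeds
    min_dist_px = seed_min_distance_um / pixel_size_um
    if min_dist_px > 0 and n_seed > 1:
        idx = np.arange(1, n_seed + 1)
        cents = np.zeros((n_seed, 2))
        depth = np.zeros(n_seed)
        for k in idx:
            ys, xs = np.nonzero(markers == k)
            vals = filled[ys, xs]
            j = int(np.argmin(vals))  # deepest pixel represents the seed
            cents[k - 1] = ys[j], xs[j]
            depth[k - 1] = vals[j]
        order = np.argsort(depth, kind="stable")  # deepest relief first
        tree = cKDTree(cents)
        keep = np.ones(n_seed, dtype=bool)
        for k in order:
            if not keep[k]:
                continue
            for j in tree.query_ball_point(cents[k], min_dist_px):
                if j != k and keep[j] and depth[j] >= depth[k]:
                    keep[j] = False
        for k in np.nonzero(~keep)[0]:
            markers[markers == k + 1] = 0
        markers = cc_label(markers > 0, connectivity=2)

    labels = watershed(relief, markers, watershed_line=True)
    return labels.astype(np.int32)


def link_frames(labels_t: np.ndarray, labels_t1: np.ndarray) -> dict:
    """Greedy maximal-overlap matching between two label images.

    A pair is linked iff its overlap covers ≥ 0.5 of the smaller region.
    Candidates are taken in order of decreasing overlap area, ties broken by
    smaller label id; each label is used at most once.  Returns a dict
    mapping label in ``labels_t`` to label in ``labels_t1``.
    """
    a = np.asarray(labels_t)
    b = np.asarray(labels_t1)
    if a.shape != b.shape:
        raise ValueError("label images must share a shape")
    fg = (a > 0) & (b > 0)
    if not fg.any():
        return {}
    pairs, counts = np.unique(
        np.stack([a[fg], b[fg]]).T, axis=0, return_counts=True
    )
    size_a = np.bincount(a.ravel())
    size_b = np.bincount(b.ravel())
    order = np.lexsort((pairs[:, 1], pairs[:, 0], -counts))
    used_a, used_b, out = set(), set(), {}
    for k in order:
        la, lb = int(pairs[k, 0]), int(pairs[k, 1])
        if la in used_a or lb in used_b:
            continue
        smaller = min(size_a[la], size_b[lb])
        if counts[k] >= 0.5 * smaller:
            out[la] = lb
            used_a.add(la)
            used_b.add(lb)
    return out


def label_adjacency(labels: np.ndarray) -> set:
    """Pairs of labels sharing a boundary (≥ 1 pixel pair across the 0-line
    or directly adjacent), as a set of sorted (i, j) tuples."""
    from scipy.ndimage import grey_dilation

    lab = np.asarray(labels)
    # bridge the 1-px watershed line so cells separated by it count as neighbors
    dil = grey_dilation(lab, size=3)
    f = np.where(lab == 0, dil, lab)
    pairs = set()
    slabs = [
        (f[:, :-1], f[:, 1:]),
        (f[:-1, :], f[1:, :]),
        (f[:-1, :-1], f[1:, 1:]),
        (f[:-1, 1:], f[1:, :-1]),
    ]
    for u, v in slabs:
        m = (u > 0) & (v > 0) & (u != v)
        if m.any():
            uv = np.unique(np.sort(np.stack([u[m], v[m]]).T, axis=1), axis=0)
            pairs.update((int(i), int(j)) for i, j in uv)
    return pairs


def build_tracks(
    label_seq: list,
    times_s: np.ndarray,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Link a sequence of label images into tracks and tabulate instances.

    Returns a tidy frame with one row per cell instance: ``cell_id, frame,
    t_s, label, centroid_x_um, centroid_y_um, area_um2, radius_um,
    edge_flag``.  Track identities are never reused.
    """
    from skimage.measure import regionprops

    rows = []
    next_id = 0
    prev_map: dict = {}
    for f, labels in enumerate(label_seq):
        ny, nx = labels.shape
        if f == 0:
            id_of = {}
        else:
            link = link_frames(label_seq[f - 1], labels)
            id_of = {
                link[lab]: prev_map[lab] for lab in link if lab in prev_map
            }
        for rp in regionprops(labels):
            lab = rp.label
            if lab not in id_of:
                id_of[lab] = next_id
                next_id += 1
            cy, cx = rp.centroid
            minr, minc, maxr, maxc = rp.bbox
            rows.append(
                {
                    "cell_id": id_of[lab],
                    "frame": f,
                    "t_s": float(times_s[f]),
                    "label": lab,
                    "centroid_x_um": (cx + 0.5) * pixel_size_um,
                    "centroid_y_um": (cy + 0.5) * pixel_size_um,
                    "area_um2": rp.area * pixel_size_um**2,
                    "edge_flag": minr == 0 or minc == 0 or maxr == ny or maxc == nx,
                }
            )
        prev_map = id_of
    df = pd.DataFrame(rows)
    if len(df):
        df["radius_um"] = np.sqrt(df["area_um2"] / np.pi)
    return df


@dataclass
class QCRules:
    """Quality-control rules for tracked cells.

    Instances violating any rule are flagged invalid (never deleted):
    implausible apical area, excessive speed relative to adjacent cells,
    implausible relative area-change rate, clipped field-of-view cells, and
    short lineages.
    """

    area_min_um2: float = 2.0
    area_max_um2: float = 150.0
    rel_speed_max_um_min: float = 5.0
    area_rate_max_per_min: float = 3.0  # |d(lnA)/dt|
    min_track_len: int = 6
    drop_edge: bool = True

    def __post_init__(self):
        if self.area_min_um2 > self.area_max_um2:
            raise ValueError("area_min exceeds area_max")


def qc_filter(
    tracks: pd.DataFrame,
    adjacency_by_frame: dict | None = None,
    rules: QCRules | None = None,
) -> pd.DataFrame:
    """Set ``valid_flag`` on a tracks table according to the QC rules.

    ``adjacency_by_frame`` maps frame -> set of (label, label) neighbor
    pairs, used for the relative-speed rule; if None the speed rule compares
    against the frame-mean velocity instead.
    """
    rules = rules or QCRules()
    df = tracks.sort_values(["cell_id", "frame"]).copy()
    valid = np.ones(len(df), dtype=bool)

    area = df["area_um2"].to_numpy()
    valid &= (area >= rules.area_min_um2) & (area <= rules.area_max_um2)

    if rules.drop_edge and "edge_flag" in df:
        valid &= ~df["edge_flag"].to_numpy().astype(bool)

    tlen = df.groupby("cell_id")["frame"].transform("size").to_numpy()
    valid &= tlen >= rules.min_track_len

    # per-instance centroid velocity (forward/backward/central differences)
    vx = np.full(len(df), np.nan)
    vy = np.full(len(df), np.nan)
    lnrate = np.full(len(df), np.nan)
    for _, idx in df.groupby("cell_id").indices.items():
        t = df["t_s"].to_numpy()[idx] / 60.0  # min
        if len(idx) < 2:
            continue
        x = df["centroid_x_um"].to_numpy()[idx]
        y = df["centroid_y_um"].to_numpy()[idx]
        la = np.log(np.clip(df["area_um2"].to_numpy()[idx], 1e-9, None))
        vx[idx] = np.gradient(x, t)
        vy[idx] = np.gradient(y, t)
        lnrate[idx] = np.gradient(la, t)

    with np.errstate(invalid="ignore"):
        valid &= ~(np.abs(lnrate) > rules.area_rate_max_per_min)

    # relative speed to neighbors
    rel = np.full(len(df), np.nan)
    if adjacency_by_frame is not None and "label" in df:
        for f, sub_idx in df.groupby("frame").indices.items():
            adj = adjacency_by_frame.get(f, set())
            nbrs: dict = {}
            for i, j in adj:
                nbrs.setdefault(i, []).append(j)
                nbrs.setdefault(j, []).append(i)
            labs = df["label"].to_numpy()[sub_idx]
            fvx = {int(l): vx[k] for l, k in zip(labs, sub_idx)}
            fvy = {int(l): vy[k] for l, k in zip(labs, sub_idx)}
            for l, k in zip(labs, sub_idx):
                nb = [m for m in nbrs.get(int(l), []) if m in fvx]
                if not nb or not np.isfinite(vx[k]):
                    continue
                mvx = np.nanmean([fvx[m] for m in nb])
                mvy = np.nanmean([fvy[m] for m in nb])
                rel[k] = np.hypot(vx[k] - mvx, vy[k] - mvy)
    else:
        for f, sub_idx in df.groupby("frame").indices.items():
            mvx = np.nanmean(vx[sub_idx])
            mvy = np.nanmean(vy[sub_idx])
            rel[sub_idx] = np.hypot(vx[sub_idx] - mvx, vy[sub_idx] - mvy)

    with np.errstate(invalid="ignore"):
        valid &= ~(rel > rules.rel_speed_max_um_min)

    df["rel_speed_um_min"] = rel
    df["lnA_rate_per_min"] = lnrate
    df["valid_flag"] = valid
    return df


def apply_label_edits(labels: np.ndarray, edits: pd.DataFrame) -> np.ndarray:
    """Apply a manual-correction table to a label image.

    ``edits`` rows carry (y_px, x_px, new_label): the connected region
    containing the pixel is reassigned to ``new_label`` (0 erases it to
    boundary).  This replaces interactive outline correction with an
    importable, scriptable edit file.
    """
    out = np.asarray(labels).copy()
    for _, row in edits.iterrows():
        y, x = int(row["y_px"]), int(row["x_px"])
        old = out[y, x]
        if old == 0:
            out[y, x] = int(row["new_label"])
        else:
            out[out == old] = int(row["new_label"])
    return out
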