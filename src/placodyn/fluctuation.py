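"""Medial/junctional intensity quantification and fluctuation analysis.

This module carries the core oscillation statistics: per-cell medial and
junctional myosin traces (baseline-subtracted against an epidermal
reference region), boxcar detrending, trough-to-trough (myosin) or
peak-to-peak (radius) cycle detection, activity classification
(amplitude × frequency against fixed thresholds), pooled fluctuation
fractions, and the phase relationship between medial myosin and the inverse
apical cell radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from shapely.geometry import Polygon

__all__ = [
    "RegionPartition",
    "partition_regions",
    "quantify_traces",
    "DetrendedTrace",
    "detrend",
    "FluctuationCycle",
    "detect_cycles",
    "classify_activity",
    "fluctuation_fractions",
    "fractions_from_counts",
    "PhaseAverage",
    "phase_average",
    "focus_colocalization",
    "MYOSIN_ACTIVITY_THRESHOLD",
    "RADIUS_ACTIVITY_THRESHOLD",
]

# activity = cycle amplitude (signal units) × frequency (min⁻¹); below these
# the behavior is classified as non-periodic
MYOSIN_ACTIVITY_THRESHOLD = 0.5
RADIUS_ACTIVITY_THRESHOLD = 0.005


# ---------------------------------------------------------------------------
# region partitioning and intensity quantification
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Medial (inward offset) and junctional (rim band) parts of a cell."""

    medial: Polygon
    junctional: object  # Polygon or MultiPolygon; empty if band_width == 0
    band_width_um: float


def partition_regions(polygon, band_width_um: float) -> RegionPartition:
    """Split a cell polygon into a medial core and a junctional band.

    The medial polygon is the cell offset inward by ``band_width_um``; the
    junctional band is the remainder.  If the offset empties the polygon
    (very small cells), the medial part is empty and the whole cell is
    junctional.
    """
    if band_width_um < 0:
        raise ValueError("band_width must be >= 0")
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon))
    if band_width_um == 0:
        return RegionPartition(poly, Polygon(), 0.0)
    medial = poly.buffer(-band_width_um, join_style=2)
    if medial.is_empty or medial.area <= 0:
        return RegionPartition(Polygon(), poly, band_width_um)
    junctional = poly.difference(medial)
    return RegionPartition(medial, junctional, band_width_um)


def quantify_traces(
    myosin_frames: list,
    label_seq: list,
    tracks: pd.DataFrame,
    baseline_mask: np.ndarray,
    pixel_size_um: float,
    band_width_um: float = 1.0,
) -> pd.DataFrame:
    """Per-instance medial and junctional myosin means, baseline-subtracted.

    For every tracked instance, the medial mask is the cell's label region
    eroded inward by ``band_width_um`` and the junctional band is the rest;
    the per-frame scalar mean of the myosin image over ``baseline_mask``
    (epidermis outside the placode) is subtracted and the result floored at
    0.  Instances whose erosion empties the medial region get NaN medial
    (missing, not zero).

    Adds ``medial_gs``, ``junctional_gs`` and ``baseline_gs`` columns.
    """
    from scipy.ndimage import binary_erosion, find_objects
    from skimage.morphology import disk

    if baseline_mask is None or not np.any(baseline_mask):
        raise ValueError("baseline_mask must be non-empty")
    band_px = max(int(round(band_width_um / pixel_size_um)), 1)
    selem = disk(band_px)

    medial_by_key: dict = {}
    junct_by_key: dict = {}
    base_by_frame: dict = {}
    for f, (img, labels) in enumerate(zip(myosin_frames, label_seq)):
        base = float(img[baseline_mask].mean())
        base_by_frame[f] = base
        for lab, sl in enumerate(find_objects(labels), start=1):
            if sl is None:
                continue
            mask = labels[sl] == lab
            medial = binary_erosion(mask, selem)
            junctional = mask & ~medial
            sub = img[sl]
            key = (f, lab)
            medial_by_key[key] = (
                max(float(sub[medial].mean()) - base, 0.0) if medial.any() else np.nan
            )
            junct_by_key[key] = (
                max(float(sub[junctional].mean()) - base, 0.0)
                if junctional.any()
                else np.nan
            )

    df = tracks.copy()
    keys = list(zip(df["frame"].astype(int), df["label"].astype(int)))
    df["medial_gs"] = [medial_by_key.get(k, np.nan) for k in keys]
    df["junctional_gs"] = [junct_by_key.get(k, np.nan) for k in keys]
    df["baseline_gs"] = [base_by_frame.get(int(f), np.nan) for f in df["frame"]]
    return df


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

@dataclass
class DetrendedTrace:
    """raw = trend + detrended, exactly; trend is a centered boxcar mean
    (window truncated at the series ends)."""

    times_s: np.ndarray
    raw: np.ndarray
    trend: np.ndarray
    detrended: np.ndarray
    window_s: float


def detrend(times_s: np.ndarray, raw: np.ndarray, window_s: float = 360.0) -> DetrendedTrace:
    """Boxcar-detrend a time series.

    The trend is the centered moving mean over ``window_s`` (default 6 min,
    longer than the longest expected fluctuation cycle), truncated at the
    series ends; the detrended series is raw − trend, so the decomposition
    reconstructs the raw series exactly.
    """
    t = np.asarray(times_s, dtype=float)
    x = np.asarray(raw, dtype=float)
    if len(t) != len(x):
        raise ValueError("times and values must be equal length")
    if len(x) < 3:
        raise ValueError("series must have at least 3 samples")
    dt = np.median(np.diff(t))
    if window_s < 2 * dt:
        raise ValueError("window must span at least two frame intervals")
    hw = int(round(window_s / 2.0 / dt))
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(i - hw, 0)
    hi = np.minimum(i + hw, n - 1)
    trend = (cs[hi + 1] - cs[lo]) / (hi - lo + 1)
    return DetrendedTrace(t, x, trend, x - trend, window_s)


# ---------------------------------------------------------------------------
# cycle detection and activity classification
# ---------------------------------------------------------------------------

@dataclass
class FluctuationCycle:
    """One full fluctuation cycle of a detrended signal.

    Myosin cycles run trough→trough, radius cycles peak→peak; phase is 0 at
    the opening extremum and advances linearly in time to 1 at the closing
    extremum.  Amplitude is max − min of the detrended signal inside the
    cycle.
    """

    kind: str
    start_idx: int
    end_idx: int
    start_t_s: float
    end_t_s: float
    length_s: float
    amplitude: float

    @property
    def frequency_per_min(self) -> float:
        return 60.0 / self.length_s

    @property
    def activity(self) -> float:
        return self.amplitude * self.frequency_per_min

    def phase_at(self, idx: np.ndarray, times_s: np.ndarray) -> np.ndarray:
        return (times_s[idx] - self.start_t_s) / (self.end_t_s - self.start_t_s)


def detect_cycles(
    trace: DetrendedTrace,
    kind: str = "myosin",
    prominence: float | None = None,
) -> list:
    """Delimit full fluctuation cycles on a detrended trace.

    Extrema are found with the given prominence (default 0.2 × the detrended
    standard deviation); consecutive troughs (myosin) or peaks (radius)
    delimit cycles.  A series with fewer than two qualifying extrema yields
    no cycles.
    """
    if kind not in ("myosin", "radius"):
        raise ValueError("kind must be 'myosin' or 'radius'")
    x = trace.detrended
    if len(x) < 5:
        raise ValueError("need at least 5 samples to detect cycles")
    if prominence is None:
        prominence = 0.2 * float(np.std(x))
    signal = -x if kind == "myosin" else x  # troughs vs peaks
    ext, _ = find_peaks(signal, prominence=prominence if prominence > 0 else None)
    cycles = []
    for i0, i1 in zip(ext[:-1], ext[1:]):
        seg = x[i0 : i1 + 1]
        cycles.append(
            FluctuationCycle(
                kind=kind,
                start_idx=int(i0),
                end_idx=int(i1),
                start_t_s=float(trace.times_s[i0]),
                end_t_s=float(trace.times_s[i1]),
                length_s=float(trace.times_s[i1] - trace.times_s[i0]),
                amplitude=float(seg.max() - seg.min()),
            )
        )
    return cycles


def classify_activity(
    n_samples: int,
    cycles: list,
    threshold: float,
) -> pd.DataFrame:
    """Per-instance activity and fluctuating/non-fluctuating classification.

    Every sample inside a detected cycle inherits that cycle's activity
    (amplitude × frequency, min⁻¹) and is fluctuating iff activity ≥
    threshold; samples outside any cycle are non-fluctuating with NaN
    activity.  A sample on the shared boundary of two cycles belongs to the
    earlier one.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    activity = np.full(n_samples, np.nan)
    cycle_id = np.full(n_samples, -1)
    fluct = np.zeros(n_samples, dtype=bool)
    for k, c in enumerate(cycles):
        sl = slice(c.start_idx, c.end_idx + 1)
        unassigned = cycle_id[sl] == -1
        idx = np.arange(c.start_idx, c.end_idx + 1)[unassigned]
        activity[idx] = c.activity
        cycle_id[idx] = k
        fluct[idx] = c.activity >= threshold
    return pd.DataFrame(
        {"activity": activity, "cycle_id": cycle_id, "fluctuating": fluct}
    )


def fluctuation_fractions(instances: pd.DataFrame) -> dict:
    """Pool cell instances and report fluctuation percentages.

    ``instances`` needs boolean columns ``fluct_myosin`` and
    ``fluct_radius`` and (optionally) ``determinable``; rows where
    ``determinable`` is False are excluded from the denominators.  Returns
    the percentage of instances with myosin fluctuations, the percentage of
    myosin-fluctuating instances that also fluctuate in radius, and the raw
    counts.  Undefined ratios (zero denominator) are NaN.
    """
    df = instances
    if "determinable" in df:
        df = df[df["determinable"].astype(bool)]
    n = len(df)
    n_myo = int(df["fluct_myosin"].sum()) if n else 0
    n_both = (
        int((df["fluct_myosin"] & df["fluct_radius"]).sum())
        if n and "fluct_radius" in df
        else 0
    )
    return {
        "n_instances": n,
        "n_myosin_fluct": n_myo,
        "n_both_fluct": n_both,
        "pct_myosin_fluct": 100.0 * n_myo / n if n else float("nan"),
        "pct_radius_given_myosin": 100.0 * n_both / n_myo if n_myo else float("nan"),
    }


def fractions_from_counts(n_instances: int, n_myosin: int, n_both: int | None = None) -> dict:
    """Fluctuation percentages from pre-tabulated pooled counts."""
    if n_instances < n_myosin or (n_both is not None and n_myosin < n_both):
        raise ValueError("counts must be nested: n_both <= n_myosin <= n_instances")
    out = {
        "n_instances": int(n_instances),
        "n_myosin_fluct": int(n_myosin),
        "pct_myosin_fluct": 100.0 * n_myosin / n_instances
        if n_instances
        else float("nan"),
    }
    if n_both is not None:
        out["n_both_fluct"] = int(n_both)
        out["pct_radius_given_myosin"] = (
            100.0 * n_both / n_myosin if n_myosin else float("nan")
        )
    return out


# ---------------------------------------------------------------------------
# phase averaging
# ---------------------------------------------------------------------------

@dataclass
class PhaseAverage:
    """Binned averages of detrended myosin and detrended inverse radius
    against myosin-cycle phase, with the estimated myosin lead.

    ``lead_cycles`` (positive = myosin ahead) comes from the first circular
    harmonic of the bin means, which interpolates below the bin width;
    ``lead_cycles_argmax`` is the coarser bin-argmax difference.
    """

    bins: pd.DataFrame
    lead_cycles: float
    lead_cycles_argmax: float
    n_cycles: int


def _wrap_half(x: float) -> float:
    return (x + 0.5) % 1.0 - 0.5


def _harmonic_peak_phase(phases: np.ndarray, values: np.ndarray) -> float:
    c = float(np.sum(values * np.cos(2 * np.pi * phases)))
    s = float(np.sum(values * np.sin(2 * np.pi * phases)))
    return (np.arctan2(s, c) / (2 * np.pi)) % 1.0


def phase_average(
    phases: np.ndarray,
    myosin_detrended: np.ndarray,
    inv_radius_detrended: np.ndarray,
    n_bins: int = 16,
    n_cycles: int | None = None,
) -> PhaseAverage:
    """Pool cycle instances into phase bins and estimate the myosin lead.

    ``phases`` are myosin-cycle phases in [0, 1) of the pooled instances;
    the two signal arrays are the matching detrended medial myosin and
    detrended inverse radius (1/radius computed before detrending).  Bin
    means carry 95% CIs (1.96·SEM).  The lead is the circular phase
    difference between the inverse-radius peak and the myosin peak, in
    [−0.5, 0.5), positive when myosin is ahead.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    ph = np.asarray(phases, dtype=float) % 1.0
    m = np.asarray(myosin_detrended, dtype=float)
    ir = np.asarray(inv_radius_detrended, dtype=float)
    ok = np.isfinite(ph) & np.isfinite(m) & np.isfinite(ir)
    ph, m, ir = ph[ok], m[ok], ir[ok]
    if len(ph) == 0:
        raise ValueError("no finite cycle instances to average")

    idx = np.minimum((ph * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        lo, hi = b / n_bins, (b + 1) / n_bins
        if n:
            mm, im = m[sel].mean(), ir[sel].mean()
            msem = m[sel].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            isem = ir[sel].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            rows.append(
                (lo, hi, mm, mm - 1.96 * msem, mm + 1.96 * msem,
                 im, im - 1.96 * isem, im + 1.96 * isem, n)
            )
        else:
            rows.append((lo, hi, *([np.nan] * 6), 0))
    bins = pd.DataFrame(
        rows,
        columns=[
            "phase_lo", "phase_hi",
            "mean_myosin", "myosin_ci_lo", "myosin_ci_hi",
            "mean_inv_radius", "inv_radius_ci_lo", "inv_radius_ci_hi",
            "n",
        ],
    )

    centers = (bins["phase_lo"] + bins["phase_hi"]).to_numpy() / 2.0
    good = bins["n"].to_numpy() > 0
    pm = _harmonic_peak_phase(centers[good], bins["mean_myosin"].to_numpy()[good])
    pi = _harmonic_peak_phase(centers[good], bins["mean_inv_radius"].to_numpy()[good])
    lead = _wrap_half(pi - pm)

    mg = bins["mean_myosin"].to_numpy()
    ig = bins["mean_inv_radius"].to_numpy()
    am = centers[np.nanargmax(mg)]
    ai = centers[np.nanargmax(ig)]
    lead_argmax = _wrap_half(ai - am)

    return PhaseAverage(
        bins=bins,
        lead_cycles=float(lead),
        lead_cycles_argmax=float(lead_argmax),
        n_cycles=int(n_cycles) if n_cycles is not None else -1,
    )


# ---------------------------------------------------------------------------
# focus colocalization
# ---------------------------------------------------------------------------

def focus_colocalization(points_a, points_b, radius_um: float) -> float:
    """Fraction of a-points with at least one b-point within ``radius_um``.

    Each a-point is tested independently; b-points may serve several
    a-points.  An empty a-set has no defined fraction and is rejected.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    if a.size == 0:
        raise ValueError("fraction undefined for an empty a-set")
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if b.size == 0:
        return 0.0
    from scipy.spatial import cKDTree

    d, _ = cKDTree(b).query(a, k=1)
    return float(np.mean(d <= radius_um))
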