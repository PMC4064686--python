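"""End-to-end analysis: movie in, fluctuation statistics out.

:class:`PlacodeAnalysis` is the model-style entry point: it is constructed
from a two-channel movie (plus the analysis parameters), and ``fit()`` runs
surface extraction → projection → segmentation → tracking → QC → intensity
quantification → detrending → cycle detection → classification → pooled
statistics, returning a :class:`PlacodeResults` that carries the estimates
(phase lead, cycle lengths, fluctuation fractions), their uncertainties
(binned 95% CIs), the intermediate tables, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fluctuation as fl
from . import geometry as geo
from . import segmentation as seg
from . import surface as surf

__all__ = ["AnalysisParams", "PlacodeAnalysis", "PlacodeResults"]


@dataclass
class AnalysisParams:
    """Tunable parameters of the measurement pipeline (units in names)."""

    projection_thickness_um: float = 1.0
    blanket_smoothness: float = 1.0          # μm height per μm lateral
    membrane_smoothing_um: float = 0.4
    seed_min_distance_um: float = 2.0
    adaptive_block_um: float = 15.0
    band_width_um: float = 1.0               # junctional band for partitioning
    detrend_window_s: float = 360.0
    threshold_myosin: float = fl.MYOSIN_ACTIVITY_THRESHOLD
    threshold_radius: float = fl.RADIUS_ACTIVITY_THRESHOLD
    prominence_rel: float = 0.2              # × detrended std
    phase_bins: int = 16
    radial_bin_width_um: float = 5.0
    area_rate_window_s: float = 60.0
    qc: seg.QCRules = field(default_factory=seg.QCRules)


@dataclass
class PlacodeResults:
    """Fitted pipeline output; see attribute docstrings below.

    tracks_ : per-instance table (geometry, intensities, flags, activity).
    cycles_ : per-cycle table (cell, kind, length, amplitude, activity).
    phase_average_ : binned phase relationship (:class:`~placodyn.fluctuation.PhaseAverage`).
    fractions_ : pooled fluctuation percentages and counts.
    radial_activity_, radial_area_rate_ : radial profiles with 95% CIs.
    """

    params: AnalysisParams
    tracks_: pd.DataFrame
    cycles_: pd.DataFrame
    phase_average_: object
    fractions_: dict
    fractions_strict_: dict
    radial_activity_: pd.DataFrame
    radial_area_rate_: pd.DataFrame
    surface_maps_: list
    label_images_: list
    lead_cycles_: float
    mean_cycle_length_s_: float
    surface_displacement_um_: float

    def summary(self) -> dict:
        """Headline numbers of the fitted analysis."""
        f = self.fractions_
        return {
            "n_instances": f["n_instances"],
            "n_myosin_fluct": f["n_myosin_fluct"],
            "n_both_fluct": f["n_both_fluct"],
            "pct_myosin_fluct": f["pct_myosin_fluct"],
            "pct_radius_given_myosin": f["pct_radius_given_myosin"],
            "pct_myosin_fluct_strict": self.fractions_strict_["pct_myosin_fluct"],
            "n_myosin_cycles": int(
                (self.cycles_["kind"] == "myosin").sum() if len(self.cycles_) else 0
            ),
            "mean_cycle_length_s": self.mean_cycle_length_s_,
            "lead_cycles": self.lead_cycles_,
            "mean_surface_displacement_um": self.surface_displacement_um_,
            "thresholds": {
                "myosin": self.params.threshold_myosin,
                "radius": self.params.threshold_radius,
            },
        }

    def summary_text(self) -> str:
        s = self.summary()
        lines = [
            "placodyn pipeline summary",
            "-" * 41,
            f"tracked placodal cell instances : {s['n_instances']}",
            f"  with myosin fluctuations      : {s['n_myosin_fluct']}"
            f" ({s['pct_myosin_fluct']:.1f}%)",
            f"  of those, radius fluctuating  : {s['n_both_fluct']}"
            f" ({s['pct_radius_given_myosin']:.1f}%)",
            f"myosin cycles pooled            : {s['n_myosin_cycles']}",
            f"mean myosin cycle length        : {s['mean_cycle_length_s']:.1f} s",
            f"myosin lead over 1/radius       : {s['lead_cycles']:.3f} cycles",
        ]
        return "\n".join(lines)


class PlacodeAnalysis:
    """Full quantitative analysis of a placode movie.

    Parameters
    ----------
    movie : a :class:`~placodyn.synthetic.SyntheticMovie` or any object with
        the same interface (``data`` (t, z, c, y, x), calibration attributes,
        ``zstack(frame, role)``).
    pit_center : (x, y) μm; defaults to the movie truth's pit when present.
    placode_mask : 2D boolean pixel mask of the placode; defaults to the
        movie truth's ellipse.  Its complement is the epidermal baseline
        region.
    params : :class:`AnalysisParams`.
    """

    def __init__(self, movie, pit_center=None, placode_mask=None,
                 params: AnalysisParams | None = None):
        self.movie = movie
        self.params = params or AnalysisParams()
        if pit_center is None:
            if getattr(movie, "truth", None) is None:
                raise ValueError("pit_center is required when the movie has no truth")
            pit_center = movie.truth.geometry.pit_center
        self.pit_center = np.asarray(pit_center, dtype=float)
        if placode_mask is None:
            if getattr(movie, "truth", None) is None:
                raise ValueError("placode_mask is required when the movie has no truth")
            placode_mask = movie.placode_pixel_mask()
        self.placode_mask = np.asarray(placode_mask, dtype=bool)

    # ------------------------------------------------------------------
    def fit(self) -> PlacodeResults:
        p = self.params
        movie = self.movie
        T = movie.n_frames
        times = np.arange(T) * movie.frame_interval_s
        px = movie.pixel_size_um

        # surface extraction + projection
        projected = [
            surf.project_movie_frame(
                movie, t, thickness_um=p.projection_thickness_um,
                smoothness_bound=p.blanket_smoothness,
            )
            for t in range(T)
        ]
        surfaces = [pf.surface for pf in projected]
        disp = [
            float(np.mean(np.abs(a.height_um - b.height_um)))
            for a, b in zip(surfaces[:-1], surfaces[1:])
        ]
        surface_displacement = float(np.mean(disp)) if disp else 0.0

        # segmentation and tracking
        labels_seq = [
            seg.segment_cells(
                pf["membrane"], pixel_size_um=px,
                membrane_smoothing_um=p.membrane_smoothing_um,
                seed_min_distance_um=p.seed_min_distance_um,
                adaptive_block_um=p.adaptive_block_um,
            )
            for pf in projected
        ]
        tracks = seg.build_tracks(labels_seq, times, px)
        adjacency = {t: seg.label_adjacency(labels_seq[t]) for t in range(T)}
        tracks = seg.qc_filter(tracks, adjacency, p.qc)

        # placode membership and pit-centered coordinates
        iy = np.clip((tracks["centroid_y_um"] / px - 0.5).round().astype(int),
                     0, self.placode_mask.shape[0] - 1)
        ix = np.clip((tracks["centroid_x_um"] / px - 0.5).round().astype(int),
                     0, self.placode_mask.shape[1] - 1)
        tracks["placode_flag"] = self.placode_mask[iy, ix]
        tracks = geo.assign_placode_coordinates(tracks, self.pit_center)

        # intensity quantification against the epidermal baseline
        myo_frames = [pf["myosin"] for pf in projected]
        tracks = fl.quantify_traces(
            myo_frames, labels_seq, tracks,
            baseline_mask=~self.placode_mask, pixel_size_um=px,
            band_width_um=p.band_width_um,
        )

        results = self._analyze_traces(tracks, times)
        tracks, cycle_rows, pooled = results

        cycles = pd.DataFrame(
            cycle_rows,
            columns=["cell_id", "kind", "start_t_s", "end_t_s",
                     "length_s", "amplitude", "activity"],
        )

        fractions = fl.fluctuation_fractions(
            tracks.rename(columns={"determinable_incl": "determinable"})
        ) if len(tracks) else fl.fractions_from_counts(0, 0, 0)
        strict = fl.fluctuation_fractions(
            tracks.rename(columns={"determinable_excl": "determinable"})
        ) if len(tracks) else fl.fractions_from_counts(0, 0, 0)

        myo_cycles = cycles[cycles["kind"] == "myosin"] if len(cycles) else cycles
        mean_cycle = float(myo_cycles["length_s"].mean()) if len(myo_cycles) else float("nan")

        if len(pooled["phase"]):
            pa = fl.phase_average(
                pooled["phase"], pooled["myosin"], pooled["inv_radius"],
                n_bins=p.phase_bins, n_cycles=len(myo_cycles),
            )
            lead = pa.lead_cycles
        else:
            pa, lead = None, float("nan")

        # radial profiles over valid placodal instances
        sel = tracks["placode_flag"] & tracks["valid_flag"]
        act = tracks.loc[sel, "activity_myosin"].to_numpy()
        rr = tracks.loc[sel, "r_um"].to_numpy()
        rate = tracks.loc[sel, "dlnA_dt_min"].to_numpy()
        radial_activity = (
            geo.radial_profile(act, rr, p.radial_bin_width_um)
            if sel.any() else pd.DataFrame()
        )
        radial_rate = (
            geo.radial_profile(rate, rr, p.radial_bin_width_um)
            if sel.any() else pd.DataFrame()
        )

        return PlacodeResults(
            params=p,
            tracks_=tracks,
            cycles_=cycles,
            phase_average_=pa,
            fractions_=fractions,
            fractions_strict_=strict,
            radial_activity_=radial_activity,
            radial_area_rate_=radial_rate,
            surface_maps_=surfaces,
            label_images_=labels_seq,
            lead_cycles_=lead,
            mean_cycle_length_s_=mean_cycle,
            surface_displacement_um_=surface_displacement,
        )

    # ------------------------------------------------------------------
    def _analyze_traces(self, tracks: pd.DataFrame, times: np.ndarray):
        """Per-track detrending, cycle detection and classification."""
        p = self.params
        n = len(tracks)
        tracks = tracks.sort_values(["cell_id", "frame"]).reset_index(drop=True)
        for col in ("detrended_myosin", "detrended_inv_radius",
                    "activity_myosin", "phase_myosin"):
            tracks[col] = np.nan
        for col in ("fluct_myosin", "fluct_radius",
                    "determinable_incl", "determinable_excl"):
            tracks[col] = False
        tracks["cycle_id_myosin"] = -1

        min_samples = max(int(round(p.detrend_window_s / self.movie.frame_interval_s)),
                          5)
        cycle_rows = []
        pooled = {"phase": [], "myosin": [], "inv_radius": []}

        for cid, idx in tracks.groupby("cell_id").indices.items():
            sub = tracks.iloc[idx]
            if not (sub["placode_flag"].all() and sub["valid_flag"].all()):
                if not (sub["placode_flag"].any() and sub["valid_flag"].any()):
                    continue
            usable = sub["placode_flag"].to_numpy() & sub["valid_flag"].to_numpy()
            if usable.sum() < min_samples:
                continue
            idx = np.asarray(idx)[usable]
            sub = tracks.iloc[idx]
            t = sub["t_s"].to_numpy()
            if np.any(np.diff(t) <= 0) or len(np.unique(np.round(np.diff(t), 6))) > 1:
                # analysis needs a contiguous, evenly sampled trace
                continue
            myo = sub["medial_gs"].to_numpy()
            if np.isnan(myo).mean() > 0.2:
                continue
            myo = pd.Series(myo).interpolate(limit_direction="both").to_numpy()
            inv_r = 1.0 / sub["radius_um"].to_numpy()

            dm = fl.detrend(t, myo, p.detrend_window_s)
            dr = fl.detrend(t, inv_r, p.detrend_window_s)
            tracks.loc[idx, "detrended_myosin"] = dm.detrended
            tracks.loc[idx, "detrended_inv_radius"] = dr.detrended

            myo_cycles = fl.detect_cycles(
                dm, "myosin", prominence=p.prominence_rel * np.std(dm.detrended))
            # radius cycles are peak-to-peak on the radius signal itself
            drad = fl.detrend(t, sub["radius_um"].to_numpy(), p.detrend_window_s)
            rad_cycles = fl.detect_cycles(
                drad, "radius", prominence=p.prominence_rel * np.std(drad.detrended))

            cm = fl.classify_activity(len(t), myo_cycles, p.threshold_myosin)
            cr = fl.classify_activity(len(t), rad_cycles, p.threshold_radius)

            tracks.loc[idx, "activity_myosin"] = cm["activity"].to_numpy()
            tracks.loc[idx, "cycle_id_myosin"] = cm["cycle_id"].to_numpy()
            tracks.loc[idx, "fluct_myosin"] = cm["fluctuating"].to_numpy()
            tracks.loc[idx, "fluct_radius"] = cr["fluctuating"].to_numpy()
            tracks.loc[idx, "determinable_incl"] = True
            span = np.zeros(len(t), dtype=bool)
            if myo_cycles:
                span[myo_cycles[0].start_idx: myo_cycles[-1].end_idx + 1] = True
            tracks.loc[idx, "determinable_excl"] = span

            for c in myo_cycles:
                cycle_rows.append([cid, "myosin", c.start_t_s, c.end_t_s,
                                   c.length_s, c.amplitude, c.activity])
                ii = np.arange(c.start_idx, c.end_idx)  # end point opens next cycle
                ph = (t[ii] - c.start_t_s) / (c.end_t_s - c.start_t_s)
                tracks.loc[idx[ii], "phase_myosin"] = ph
                pooled["phase"].append(ph)
                pooled["myosin"].append(dm.detrended[ii])
                pooled["inv_radius"].append(dr.detrended[ii])
            for c in rad_cycles:
                cycle_rows.append([cid, "radius", c.start_t_s, c.end_t_s,
                                   c.length_s, c.amplitude, c.activity])

            rates = geo.area_change_rate(
                t, sub["area_um2"].to_numpy(), p.area_rate_window_s)
            tracks.loc[idx, "dA_dt_um2_min"] = rates["dA_dt_um2_min"].to_numpy()
            tracks.loc[idx, "dlnA_dt_min"] = rates["dlnA_dt_min"].to_numpy()

        for k in pooled:
            pooled[k] = (np.concatenate(pooled[k]) if pooled[k]
                         else np.array([]))
        if "dlnA_dt_min" not in tracks:
            tracks["dlnA_dt_min"] = np.nan
            tracks["dA_dt_um2_min"] = np.nan
        return tracks, cycle_rows, pooled
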