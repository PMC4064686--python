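"""Detrending, cycle detection, activity classification and phase averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placodyn.fluctuation import (
    classify_activity,
    detect_cycles,
    detrend,
    fluctuation_fractions,
    focus_colocalization,
    fractions_from_counts,
    partition_regions,
    phase_average,
)


class TestPartitionRegions:
    SQUARE = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]

    def test_zero_band_everything_medial(self):
        part = partition_regions(self.SQUARE, 0.0)
        assert part.medial.area == pytest.approx(100.0)
        assert part.junctional.is_empty

    def test_square_with_unit_band(self):
        part = partition_regions(self.SQUARE, 1.0)
        assert part.medial.area == pytest.approx(64.0, rel=1e-9)
        assert part.junctional.area == pytest.approx(36.0, rel=1e-9)

    def test_areas_additive(self):
        poly = [(0, 0), (8, 1), (9, 7), (2, 9), (-1, 4)]
        from shapely.geometry import Polygon

        for band in (0.5, 1.0, 2.0):
            part = partition_regions(poly, band)
            total = part.medial.area + part.junctional.area
            assert total == pytest.approx(Polygon(poly).area, abs=1e-9)

    def test_erosion_to_nothing_keeps_cell_junctional(self):
        part = partition_regions(self.SQUARE, 6.0)
        assert part.medial.is_empty
        assert part.junctional.area == pytest.approx(100.0)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            partition_regions(self.SQUARE, -1.0)


class TestDetrend:
    T = np.arange(0, 900, 20.0)

    def test_constant_series_detrends_to_zero(self):
        out = detrend(self.T, np.full(len(self.T), 7.0))
        np.testing.assert_allclose(out.detrended, 0.0, atol=1e-12)

    def test_linear_ramp_zero_at_interior(self):
        out = detrend(self.T, 2.0 + 0.05 * self.T, window_s=360.0)
        hw = int(round(360.0 / 2 / 20.0))
        np.testing.assert_allclose(out.detrended[hw:-hw], 0.0, atol=1e-9)

    def test_decomposition_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=len(self.T))
        out = detrend(self.T, x)
        np.testing.assert_array_equal(out.detrended, x - out.trend)
        np.testing.assert_allclose(out.trend + out.detrended, x, rtol=1e-14)

    def test_sinusoid_amplitude_retained(self):
        x = 3.0 * np.sin(2 * np.pi * self.T / 150.0)
        out = detrend(self.T, x, window_s=360.0)
        hw = int(round(360.0 / 2 / 20.0))
        inner = out.detrended[hw:-hw]
        assert inner.max() >= 0.8 * 3.0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            detrend(self.T, np.ones(len(self.T)), window_s=30.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60))
    def test_decomposition_exact_property(self, values):
        x = np.asarray(values)
        t = np.arange(len(x)) * 20.0
        out = detrend(t, x)
        np.testing.assert_array_equal(out.detrended, x - out.trend)


def sinusoid_trace(period=150.0, amp=1.0, duration=900.0, dt=20.0, phase=0.0,
                   raw=False):
    t = np.arange(0, duration, dt)
    x = amp * np.sin(2 * np.pi * (t / period + phase))
    if raw:  # a trend-free oscillation, bypassing boxcar attenuation
        from placodyn.fluctuation import DetrendedTrace

        return DetrendedTrace(t, x, np.zeros_like(x), x, 360.0)
    return detrend(t, x)


class TestDetectCycles:
    def test_sinusoid_cycle_lengths_within_one_frame(self):
        tr = sinusoid_trace()
        cycles = detect_cycles(tr, "myosin")
        assert len(cycles) >= 4
        for c in cycles:
            assert c.length_s == pytest.approx(150.0, abs=20.0)

    def test_monotonic_series_has_no_cycles(self):
        t = np.arange(0, 400, 20.0)
        tr = detrend(t, np.linspace(0, 1, len(t)) ** 2)
        assert detect_cycles(tr, "myosin") == []

    def test_amplitude_matches_peak_to_peak(self):
        tr = sinusoid_trace(amp=2.5, raw=True)
        for c in detect_cycles(tr, "radius"):
            assert c.amplitude == pytest.approx(5.0, rel=0.15)

    def test_cycles_disjoint_and_ordered(self):
        tr = sinusoid_trace()
        cycles = detect_cycles(tr, "myosin")
        for a, b in zip(cycles[:-1], cycles[1:]):
            assert a.end_idx == b.start_idx
            assert a.start_t_s < b.start_t_s

    def test_myosin_cycles_delimited_by_local_troughs(self):
        tr = sinusoid_trace(raw=True)
        x = tr.detrended
        cycles = detect_cycles(tr, "myosin")
        assert cycles
        for c in cycles:
            for i in (c.start_idx, c.end_idx):
                assert x[i] <= x[i - 1] and x[i] <= x[i + 1]

    def test_radius_cycles_delimited_by_local_peaks(self):
        tr = sinusoid_trace(raw=True)
        x = tr.detrended
        cycles = detect_cycles(tr, "radius")
        assert cycles
        for c in cycles:
            for i in (c.start_idx, c.end_idx):
                assert x[i] >= x[i - 1] and x[i] >= x[i + 1]


class TestClassifyActivity:
    def _cycle(self, amplitude, length_s):
        from placodyn.fluctuation import FluctuationCycle

        n = int(length_s / 20) + 1
        return FluctuationCycle("myosin", 0, n - 1, 0.0, length_s, length_s,
                                amplitude)

    def test_strong_cycle_is_fluctuating_at_the_threshold(self):
        c = self._cycle(1.5, 150.0)
        assert c.activity == pytest.approx(0.6)
        out = classify_activity(9, [c], threshold=0.5)
        assert out["fluctuating"][: 8].all()

    def test_weak_cycle_below_threshold(self):
        c = self._cycle(0.5, 300.0)
        assert c.activity == pytest.approx(0.1)
        out = classify_activity(16, [c], threshold=0.5)
        assert not out["fluctuating"].any()

    def test_instances_outside_cycles_non_fluctuating(self):
        c = self._cycle(5.0, 100.0)
        out = classify_activity(20, [c], threshold=0.5)
        assert not out["fluctuating"][c.end_idx + 1:].any()
        assert np.isnan(out["activity"][c.end_idx + 1:]).all()

    def test_raising_threshold_monotone_over_sweep(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 900, 20.0)
        tr = detrend(t, np.sin(2 * np.pi * t / 150) + 0.3 * rng.normal(size=len(t)))
        cycles = detect_cycles(tr, "myosin")
        counts = [
            classify_activity(len(t), cycles, th)["fluctuating"].sum()
            for th in np.linspace(0.05, 2.0, 20)
        ]
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_activity(5, [], threshold=0.0)


class TestFractions:
    def test_wildtype_printed_counts(self):
        out = fractions_from_counts(2877, 1849, 929)
        assert round(out["pct_myosin_fluct"]) == 64

    def test_mt_depleted_printed_counts(self):
        out = fractions_from_counts(3711, 1584, 1106)
        assert round(out["pct_myosin_fluct"]) == 43

    def test_all_non_fluctuating(self):
        df = pd.DataFrame(
            {"fluct_myosin": [False] * 5, "fluct_radius": [False] * 5}
        )
        out = fluctuation_fractions(df)
        assert out["pct_myosin_fluct"] == 0.0
        assert np.isnan(out["pct_radius_given_myosin"])

    def test_conditional_nested(self):
        df = pd.DataFrame(
            {"fluct_myosin": [True, True, False, True],
             "fluct_radius": [True, False, True, False]}
        )
        out = fluctuation_fractions(df)
        assert out["n_both_fluct"] <= out["n_myosin_fluct"] <= out["n_instances"]

    def test_inverted_counts_rejected(self):
        with pytest.raises(ValueError):
            fractions_from_counts(10, 20)


class TestPhaseAverage:
    def _pooled(self, lag, n=4000, seed=0, noise=0.05):
        rng = np.random.default_rng(seed)
        ph = rng.uniform(0, 1, n)
        myo = np.cos(2 * np.pi * (ph - 0.5)) + noise * rng.normal(size=n)
        ir = np.cos(2 * np.pi * (ph - 0.5 - lag)) + noise * rng.normal(size=n)
        return ph, myo, ir

    def test_recovers_one_eighth_cycle_lag(self):
        ph, myo, ir = self._pooled(0.125)
        pa = phase_average(ph, myo, ir, n_bins=16)
        assert pa.lead_cycles == pytest.approx(0.125, abs=0.03)
        assert pa.lead_cycles > 0

    def test_zero_lag(self):
        ph, myo, ir = self._pooled(0.0)
        pa = phase_average(ph, myo, ir, n_bins=16)
        assert pa.lead_cycles == pytest.approx(0.0, abs=0.03)

    def test_bin_means_match_groupby_oracle(self):
        ph, myo, ir = self._pooled(0.2, n=600)
        pa = phase_average(ph, myo, ir, n_bins=8)
        oracle = pd.DataFrame(
            {"bin": np.minimum((ph * 8).astype(int), 7), "m": myo, "i": ir}
        ).groupby("bin").mean()
        for b in oracle.index:
            assert pa.bins["mean_myosin"].iloc[b] == pytest.approx(
                oracle["m"][b], rel=1e-12)
            assert pa.bins["mean_inv_radius"].iloc[b] == pytest.approx(
                oracle["i"][b], rel=1e-12)

    def test_counts_conserved(self):
        ph, myo, ir = self._pooled(0.1, n=500)
        pa = phase_average(ph, myo, ir, n_bins=16)
        assert pa.bins["n"].sum() == 500

    def test_too_few_bins_rejected(self):
        ph, myo, ir = self._pooled(0.1, n=50)
        with pytest.raises(ValueError):
            phase_average(ph, myo, ir, n_bins=3)


class TestFocusColocalization:
    def test_identical_sets_full_overlap(self):
        pts = np.random.default_rng(0).uniform(0, 10, (30, 2))
        assert focus_colocalization(pts, pts, 0.5) == 1.0

    def test_empty_reference_set(self):
        pts = [(0.0, 0.0), (1.0, 1.0)]
        assert focus_colocalization(pts, np.empty((0, 2)), 1.0) == 0.0

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError):
            focus_colocalization(np.empty((0, 2)), [(0.0, 0.0)], 1.0)

    def test_matches_poisson_null_over_seeds(self):
        """For uniform random points, the hit fraction follows the Poisson
        null 1 - exp(-lambda*pi*r^2) within 3 sigma over 100 seeds."""
        lam = 0.5  # b-points per um^2
        r = 0.6
        side = 30.0
        n_a = 60
        expected = 1 - np.exp(-lam * np.pi * r**2)
        fractions = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.uniform(r, side - r, (n_a, 2))  # keep away from edges
            b = rng.uniform(0, side, (int(lam * side * side), 2))
            fractions.append(focus_colocalization(a, b, r))
        mean = np.mean(fractions)
        sem = np.std(fractions, ddof=1) / 10.0
        assert abs(mean - expected) <= 3 * sem
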