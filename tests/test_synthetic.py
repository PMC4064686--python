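"""Synthetic epithelium, dynamics and rendering."""

import numpy as np
import pytest

import placodyn as pl
from placodyn.synthetic import RenderOptics, truth_subset


def shoelace(coords):
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestGenerateEpithelium:
    def test_single_cell_is_the_domain(self):
        g = pl.generate_epithelium(1, domain=(10.0, 20.0))
        assert g.n_cells == 1
        assert g.areas()[0] == pytest.approx(200.0)
        assert g.adjacency.number_of_edges() == 0

    def test_unjittered_lattice_interior_cells_equal(self):
        g = pl.generate_epithelium(100, domain=(50.0, 50.0), jitter=0.0, seed=1)
        a = g.areas()
        deg = dict(g.adjacency.degree())
        interior = [
            i for i in range(g.n_cells)
            if deg[i] == 6 and all(deg[j] == 6 for j in g.adjacency[i])
        ]
        assert len(interior) > 10
        assert np.ptp(a[interior]) < 1e-6 * a[interior].mean()

    @pytest.mark.parametrize("n,seed", [(50, 0), (100, 1), (250, 7)])
    def test_areas_tile_domain(self, n, seed):
        g = pl.generate_epithelium(n, domain=(60.0, 40.0), seed=seed)
        total = sum(shoelace(g.vertices[c]) for c in g.cells)
        assert total == pytest.approx(2400.0, rel=1e-6)

    def test_adjacency_symmetric_and_edge_induced(self):
        from shapely.geometry import Polygon

        g = pl.generate_epithelium(60, domain=(40.0, 40.0), seed=2)
        for i, j in g.adjacency.edges:
            inter = Polygon(g.vertices[g.cells[i]]).intersection(
                Polygon(g.vertices[g.cells[j]])
            )
            assert inter.length > 0  # shared boundary segment

    def test_deterministic_for_fixed_seed(self):
        g1 = pl.generate_epithelium(80, seed=5)
        g2 = pl.generate_epithelium(80, seed=5)
        np.testing.assert_array_equal(g1.vertices, g2.vertices)

    def test_pit_inside_placode_hull(self):
        g = pl.generate_epithelium(250, seed=7)
        from shapely.geometry import MultiPoint, Point

        hull = MultiPoint(
            [tuple(c) for c in g.centroids()[sorted(g.placode_ids)]]
        ).convex_hull
        assert hull.contains(Point(*g.pit_center))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pl.generate_epithelium(10, domain=(-5.0, 5.0))
        with pytest.raises(ValueError):
            pl.generate_epithelium(0)
        with pytest.raises(ValueError):
            pl.generate_epithelium(10, jitter=0.9)
        with pytest.raises(ValueError):  # > 1 cell per um^2 is unreachable
            pl.generate_epithelium(10_000, domain=(10.0, 10.0))


class TestSimulateDynamics:
    def test_frame_count_includes_t0(self):
        g = pl.generate_epithelium(30, domain=(30.0, 30.0), seed=0)
        tr = pl.simulate_dynamics(g, frame_interval=20.0, duration=900.0, seed=0)
        assert tr.n_frames == 46

    def test_zero_amplitude_freezes_areas(self):
        g = pl.generate_epithelium(30, domain=(30.0, 30.0), seed=0)
        tr = pl.simulate_dynamics(
            g, pl.OscillationParams(myosin_amplitude=0.0), duration=400.0, seed=0
        )
        assert np.ptp(tr.area, axis=0).max() < 1e-9
        assert np.ptp(tr.polygon_areas(), axis=0).max() < 1e-6

    def test_cross_correlation_lag_matches_lag_cycles(self):
        """Dense-sampling cross-correlation between the analytic myosin and
        -area traces recovers lag_cycles x period."""
        g = pl.generate_epithelium(60, seed=1)
        params = pl.OscillationParams(period_sd=0.0, ratchet_fraction=0.0)
        tr = pl.simulate_dynamics(g, params, duration=900.0, seed=1, relax_iter=1)
        cell = sorted(g.placode_ids)[0]
        t = np.arange(0.0, 600.0, 1.0)
        myo, area = tr.continuous_traces(cell, t)
        x = myo - myo.mean()
        y = -(area - area.mean())
        cc = np.correlate(y, x, "full")
        # restrict to lags within one period to pick the principal peak
        lags = np.arange(-len(t) + 1, len(t))
        keep = np.abs(lags) <= 0.75 * params.period_mean
        lag = lags[keep][np.argmax(cc[keep])]
        expected = params.lag_cycles * params.period_mean
        assert lag == pytest.approx(expected, abs=0.02 * params.period_mean)

    def test_phase_lag_fidelity_on_truth_traces(self):
        """With period_sd = 0 the analytic myosin and inverse-radius traces
        differ in phase by lag_cycles to within 0.01 cycles."""
        g = pl.generate_epithelium(60, seed=2)
        params = pl.OscillationParams(period_sd=0.0, lag_cycles=0.125)
        tr = pl.simulate_dynamics(g, params, duration=900.0, seed=2, relax_iter=1)
        t = np.arange(0.0, 750.0, 1.0)
        T = params.period_mean

        def ph(s):
            # linear trend removed so the ratchet drift cannot bias the phase
            s = s - np.polyval(np.polyfit(t, s, 1), t)
            return np.arctan2(
                np.sum(s * np.sin(2 * np.pi * t / T)),
                np.sum(s * np.cos(2 * np.pi * t / T)),
            ) / (2 * np.pi)

        for cell in sorted(g.placode_ids)[:5]:
            myo, area = tr.continuous_traces(cell, t)
            inv_r = 1.0 / np.sqrt(area / np.pi)
            diff = (ph(inv_r) - ph(myo) + 0.5) % 1.0 - 0.5
            assert diff == pytest.approx(params.lag_cycles, abs=0.01)

    def test_tiling_conserved_every_frame(self, default_truth):
        w, h = default_truth.geometry.domain
        totals = default_truth.polygon_areas().sum(axis=1)
        assert np.all(np.abs(totals - w * h) <= 0.005 * w * h)

    def test_negative_area_parameters_rejected(self):
        g = pl.generate_epithelium(30, domain=(30.0, 30.0), seed=0)
        with pytest.raises(ValueError, match="area"):
            pl.simulate_dynamics(
                g,
                pl.OscillationParams(constriction_gain=50.0, ratchet_fraction=1.0),
                duration=900.0,
                seed=0,
            )

    def test_duration_precondition(self):
        g = pl.generate_epithelium(10, domain=(20.0, 20.0), seed=0)
        with pytest.raises(ValueError):
            pl.simulate_dynamics(g, duration=100.0, seed=0)


class TestRenderMovie:
    def _flat_scene(self, z_slice=4, **optics_kw):
        g = pl.generate_epithelium(40, domain=(30.0, 30.0), seed=4)
        tr = pl.simulate_dynamics(g, duration=320.0, seed=4)
        ny = nx = int(30.0 / 0.25)
        optics = RenderOptics(
            surface_height=np.full((ny, nx), float(z_slice)),
            photon_noise_scale=0.0, read_noise=0.0,
            psf_sigma_um=0.0, psf_sigma_z_um=0.0,
            background=0.0, flow_blob_fraction=0.0,
            **optics_kw,
        )
        return tr, optics

    def test_flat_clean_render_confines_membrane_to_one_slice(self):
        tr, optics = self._flat_scene(z_slice=4)
        mv = pl.render_movie(truth_subset(tr, [0]), optics, seed=0)
        mem = mv.data[0, :, 0]
        assert mem[4].max() > 0
        for z in range(mem.shape[0]):
            if z != 4:
                assert mem[z].max() == 0
        # and membrane only on boundary pixels
        labels = mv.truth_labels(0)
        from skimage.segmentation import find_boundaries

        boundary = find_boundaries(labels, mode="thick") | (labels == 0)
        assert np.all((mem[4] > 0) <= boundary)

    def test_clean_medial_remeasure_matches_truth_within_1pct(self):
        """Painted-mask oracle: re-measuring the rendered medial mean (no
        noise, no blur, flat surface) recovers the generating value."""
        from scipy.ndimage import binary_erosion, find_objects
        from skimage.morphology import disk
        from skimage.segmentation import find_boundaries

        tr, optics = self._flat_scene(z_slice=4)
        mv = pl.render_movie(truth_subset(tr, [0]), optics, seed=0)
        myo = mv.data[0, 4, 1]
        labels = mv.truth_labels(0)
        boundary = find_boundaries(labels, mode="thick") | (labels == 0)
        band_px = int(round(optics.medial_band_um / optics.pixel_size_um))
        placodal = sorted(tr.geometry.placode_ids)
        checked = 0
        for ci, sl in enumerate(find_objects(labels)):
            if sl is None or ci not in placodal:
                continue
            mask = (labels[sl] == ci + 1) & ~boundary[sl]
            medial = binary_erosion(mask, disk(band_px))
            if medial.sum() < 20:
                continue
            measured = myo[sl][medial].mean()
            assert measured == pytest.approx(tr.myosin[0, ci], rel=0.01)
            checked += 1
        assert checked > 10

    def test_same_seed_renders_bit_identical(self):
        g = pl.generate_epithelium(30, domain=(20.0, 20.0), seed=5)
        tr = truth_subset(
            pl.simulate_dynamics(g, duration=320.0, seed=5), [0, 1]
        )
        optics = RenderOptics(n_z=8)
        a = pl.render_movie(tr, optics, seed=11)
        b = pl.render_movie(tr, optics, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_surface_out_of_stack_rejected(self):
        tr, optics = self._flat_scene(z_slice=4)
        optics.surface_height = optics.surface_height + 100.0
        with pytest.raises(ValueError, match="z range"):
            pl.render_movie(truth_subset(tr, [0]), optics, seed=0)


class TestFixedPlacode:
    def test_wildtype_gradient_clusters_small_apices_near_pit(self):
        from scipy.stats import spearmanr

        _, geom, truth = pl.make_fixed_placode("wildtype_gradient", 150, seed=2)
        plac = truth[truth["placode_flag"]]
        ids = plac["cell_id"].to_numpy()
        r = np.hypot(*(geom.centroids()[ids] - geom.pit_center).T)
        rho = spearmanr(plac["area_um2"], r).statistic
        assert rho > 0.5

    def test_dispersed_pattern_uncorrelated_with_pit(self):
        from scipy.stats import spearmanr

        _, geom, truth = pl.make_fixed_placode("dispersed", 150, seed=2)
        plac = truth[truth["placode_flag"]]
        ids = plac["cell_id"].to_numpy()
        r = np.hypot(*(geom.centroids()[ids] - geom.pit_center).T)
        rho = spearmanr(plac["area_um2"], r).statistic
        assert abs(rho) <= 0.15

    def test_same_seed_same_area_multiset(self):
        _, _, t1 = pl.make_fixed_placode("wildtype_gradient", 120, seed=9)
        _, _, t2 = pl.make_fixed_placode("dispersed", 120, seed=9)
        a1 = np.sort(t1[t1["placode_flag"]]["area_um2"].to_numpy())
        a2 = np.sort(t2[t2["placode_flag"]]["area_um2"].to_numpy())
        np.testing.assert_allclose(a1, a2)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            pl.make_fixed_placode("dispersed", 10)
        with pytest.raises(ValueError):
            pl.make_fixed_placode("nonsense", 100)
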