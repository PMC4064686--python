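"""Shared fixtures: synthetic scenes at the study's default conditions and a
smaller scene for cheaper integration tests.  All are session-scoped because
rendering and analysing movies dominates the suite's runtime."""

from __future__ import annotations

import numpy as np
import pytest

import placodyn as pl
from placodyn.synthetic import RenderOptics, truth_subset

SEED = 7


@pytest.fixture(scope="session")
def default_movie():
    """The reference study scene: ~150 placodal cells, 80x80 um, 15 min."""
    return pl.default_scene(seed=SEED)


@pytest.fixture(scope="session")
def default_results(default_movie):
    return pl.PlacodeAnalysis(default_movie).fit()


@pytest.fixture(scope="session")
def default_truth():
    geom = pl.generate_epithelium(250, seed=SEED)
    return pl.simulate_dynamics(geom, pl.OscillationParams(), 20.0, 900.0, seed=SEED)


@pytest.fixture(scope="session")
def clean_frame(default_truth):
    """Noiseless, blur-free single-frame render of the default scene."""
    optics = RenderOptics(
        photon_noise_scale=0.0, read_noise=0.0,
        psf_sigma_um=0.0, psf_sigma_z_um=0.0, flow_blob_fraction=0.0,
    )
    return pl.render_movie(truth_subset(default_truth, [0]), optics, seed=SEED)


@pytest.fixture(scope="session")
def noisy_frame(default_truth):
    """Default-noise single-frame render of the default scene."""
    return pl.render_movie(truth_subset(default_truth, [0]), RenderOptics(), seed=SEED)


@pytest.fixture(scope="session")
def small_movie():
    """A cheaper scene for integration tests: 100 cells on 50x50 um, 11 min."""
    geom = pl.generate_epithelium(100, domain=(50.0, 50.0), seed=3)
    truth = pl.simulate_dynamics(geom, pl.OscillationParams(), 20.0, 660.0, seed=3)
    return pl.render_movie(truth, RenderOptics(), seed=3)


def iou_recovery(truth_labels: np.ndarray, pred_labels: np.ndarray):
    """Fraction of truth cells matched by a predicted label with IoU >= 0.8
    (maximal-overlap assignment), plus the per-cell IoUs."""
    fg = (truth_labels > 0) & (pred_labels > 0)
    st = np.bincount(truth_labels.ravel())
    sp = np.bincount(pred_labels.ravel(), minlength=int(pred_labels.max()) + 1)
    best: dict = {}
    if fg.any():
        pairs, counts = np.unique(
            np.stack([truth_labels[fg], pred_labels[fg]]).T, axis=0,
            return_counts=True,
        )
        for (ti, pi), c in zip(pairs, counts):
            if c > best.get(ti, (0, 0))[0]:
                best[int(ti)] = (int(c), int(pi))
    ious = []
    for ti in range(1, int(truth_labels.max()) + 1):
        c, pi = best.get(ti, (0, 0))
        ious.append(c / (st[ti] + sp[pi] - c) if c else 0.0)
    ious = np.asarray(ious)
    return float((ious >= 0.8).mean()), ious
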