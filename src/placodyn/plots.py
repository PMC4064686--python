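"""Static figure exports: per-cell heat maps, cumulative histograms,
phase-average plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["paint_cell_values", "plot_heatmap", "plot_cumulative", "plot_phase_average"]


def paint_cell_values(labels: np.ndarray, values: dict) -> np.ndarray:
    """Paint a per-cell scalar onto the label image (NaN outside cells)."""
    lut = np.full(int(labels.max()) + 1, np.nan)
    for lab, v in values.items():
        if 0 < lab < len(lut):
            lut[lab] = v
    return lut[labels]


def plot_heatmap(labels, values: dict, path, title: str = "", unit: str = "µm²"):
    img = paint_cell_values(labels, values)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(img, cmap="viridis")
    ax.set_title(title)
    ax.axis("off")
    fig.colorbar(im, ax=ax, label=unit, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_cumulative(samples: dict, path, xlabel: str = "apical area (µm²)"):
    """Cumulative percentage curves for named samples."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, x in samples.items():
        xs = np.sort(np.asarray(x))
        ax.step(xs, 100.0 * np.arange(1, len(xs) + 1) / len(xs), label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative % of cells")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_phase_average(phase_avg, path):
    """Binned detrended myosin and inverse radius vs myosin-cycle phase."""
    b = phase_avg.bins
    centers = (b["phase_lo"] + b["phase_hi"]) / 2
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(centers, b["mean_myosin"], color="tab:blue", label="medial myosin (detrended)")
    ax.fill_between(centers, b["myosin_ci_lo"], b["myosin_ci_hi"],
                    color="tab:blue", alpha=0.2)
    ax2 = ax.twinx()
    ax2.plot(centers, b["mean_inv_radius"], color="tab:red",
             label="1/radius (detrended)")
    ax2.fill_between(centers, b["inv_radius_ci_lo"], b["inv_radius_ci_hi"],
                     color="tab:red", alpha=0.2)
    ax.set_xlabel("phase of myosin fluctuation cycle")
    ax.set_ylabel("myosin (gs)", color="tab:blue")
    ax2.set_ylabel("1/radius (µm⁻¹)", color="tab:red")
    ax.set_title(f"myosin lead: {phase_avg.lead_cycles:.3f} cycles")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
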