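"""Topographic-map rendering of sensor-level results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .synth_meg import SensorLayout  # noqa: E402


def plot_sensor_values(
    layout: SensorLayout,
    values: np.ndarray,
    path: str | Path,
    highlight: list[int] | None = None,
    title: str = "",
    cmap: str = "RdBu_r",
) -> None:
    """Scatter topomap of per-sensor values; ``highlight`` sensors get rings."""
    fig, ax = plt.subplots(figsize=(4, 4))
    vmax = float(np.nanmax(np.abs(values))) or 1.0
    sc = ax.scatter(
        layout.positions[:, 0], layout.positions[:, 1],
        c=values, cmap=cmap, vmin=-vmax, vmax=vmax, s=60,
    )
    if highlight:
        ax.scatter(
            layout.positions[highlight, 0], layout.positions[highlight, 1],
            facecolors="none", edgecolors="k", s=140, linewidths=1.5,
        )
    circle = plt.Circle((0, 0), 1.02, fill=False, color="gray", lw=1)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.7, label="dB")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_significance_sequence(
    layout: SensorLayout,
    mask: np.ndarray,
    centers_ms: np.ndarray,
    path: str | Path,
    title: str = "",
) -> None:
    """One panel per frame with significant sensors filled."""
    n_frames = mask.shape[0]
    ncols = min(n_frames, 9)
    nrows = int(np.ceil(n_frames / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(1.6 * ncols, 1.8 * nrows))
    axes = np.atleast_1d(axes).ravel()
    for f in range(n_frames):
        ax = axes[f]
        ax.scatter(layout.positions[:, 0], layout.positions[:, 1], s=6, c="lightgray")
        sig = np.flatnonzero(mask[f])
        if sig.size:
            ax.scatter(layout.positions[sig, 0], layout.positions[sig, 1], s=10, c="crimson")
        ax.set_title(f"{int(centers_ms[f])} ms", fontsize=7)
        ax.set_aspect("equal")
        ax.axis("off")
    for ax in axes[n_frames:]:
        ax.axis("off")
    fig.suptitle(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
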