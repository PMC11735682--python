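"""Figure exports: SNR heat maps with ROI outlines, box-and-whisker plots.

Plotting is display-only; in particular the IQR outlier convention in the
box plots (points > 1.5x outside the interquartile range drawn as filled
circles) never removes data from any statistical test.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["save_snr_map", "save_parameter_boxplot"]


def save_snr_map(snr_values: np.ndarray, path: str | Path, rois=None, electrode_px=None,
                 vmax: float | None = None) -> Path:
    """SNR encoded as color, warmer = higher, with accepted ROIs outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(snr_values, cmap="hot", vmin=0, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="SNR")
    if rois:
        for roi in rois:
            if not getattr(roi, "accepted", True):
                continue
            for r, c in roi.group.pixels:
                ax.add_patch(plt.Rectangle((c - 0.5, r - 0.5), 1, 1, fill=False,
                                           edgecolor="black", linewidth=0.8))
    if electrode_px is not None:
        ax.plot(electrode_px[1], electrode_px[0], "k*", markersize=12)
    ax.set_xticks([]), ax.set_yticks([])
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def save_parameter_boxplot(units: pd.DataFrame, parameter: str, by: str, path: str | Path) -> Path:
    """Box-and-whisker per group; IQR outliers drawn separately as filled
    circles (they remain in all analyses)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [(label, grp[parameter].to_numpy()) for label, grp in units.groupby(by, sort=True)]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1.5, 4))
    ax.boxplot(
        [v for _, v in groups],
        tick_labels=[str(label) for label, _ in groups],
        whis=1.5,
        flierprops=dict(marker="o", markerfacecolor="black", markersize=4),
    )
    ax.set_ylabel(parameter)
    ax.set_xlabel(by)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
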