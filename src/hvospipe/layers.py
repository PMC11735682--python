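"""Cortical-layer assignment and the analysis-ready cell table.

Layer boundaries are an *input*: they are identified visually on
gradient-contrast / fluorescence images (cell density, L4 barrels) and
supplied as geometry — either horizontal bands or a per-column polyline
of boundary rows.  Bands are ordered from the pia downward, e.g.
["L2/3", "L4", "L5"].  A centroid exactly on a boundary is assigned to
the band above it (toward the pia), deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import EpspParams

__all__ = ["LayerGeometry", "assign_layer", "build_cell_table", "CELL_TABLE_COLUMNS"]

ANALYSIS_LAYERS = ("L2/3", "L4")


@dataclass
class LayerGeometry:
    """Ordered bands separated by boundary rows.

    ``boundaries[i]`` separates ``layers[i]`` (above) from ``layers[i+1]``
    (below); each boundary is either a scalar row or an array of rows,
    one per image column.
    """

    layers: tuple[str, ...] = ("L2/3", "L4", "L5")
    boundaries: list[float | np.ndarray] = field(default_factory=lambda: [30.0, 55.0])

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.layers) - 1:
            raise ValueError("need exactly one boundary fewer than layers")

    def boundary_row(self, i: int, col: float) -> float:
        b = self.boundaries[i]
        if np.ndim(b) == 0:
            return float(b)
        b = np.asarray(b, dtype=float)
        return float(np.interp(col, np.arange(b.size), b))


def assign_layer(centroid_px: tuple[float, float], geometry: LayerGeometry) -> str:
    """Band label for a centroid given in pixel coordinates (row, col)."""
    row, col = centroid_px
    for i in range(len(geometry.boundaries)):
        if row <= geometry.boundary_row(i, col):  # on-boundary -> band above
            return geometry.layers[i]
    return geometry.layers[-1]


CELL_TABLE_COLUMNS = [
    "roi_id",
    "slice_id",
    "genotype",
    "sex",
    "residence_layer",
    "stimulation_layer",
    "in_analysis",
    "amplitude_pct",
    "latency_ms",
    "rise_time_ms",
    "decay_time_ms",
    "half_width_ms",
    "distance_um",
    "dn_latency_ms_per_um",
    "n_pixels",
    "area_um2",
    "centroid_row_um",
    "centroid_col_um",
    "mean_snr",
]

_REQUIRED_METADATA = ("slice_id", "genotype", "sex", "stimulation_layer")


def build_cell_table(
    rois,
    params: dict[int, EpspParams],
    metadata: dict,
    geometry: LayerGeometry,
    pixel_pitch: float,
) -> pd.DataFrame:
    """One row per *accepted* ROI, joined with kinetics and slice metadata.

    L5 cells are retained but flagged ``in_analysis=False``; the group
    statistics operate on L2/3 and L4 only.  Missing metadata raises an
    error naming the slice.
    """
    missing = [key for key in _REQUIRED_METADATA if key not in metadata]
    if missing:
        raise KeyError(
            f"slice {metadata.get('slice_id', '<unknown>')!r} missing metadata: {missing}"
        )
    rows = []
    for roi in rois:
        if not roi.accepted:
            continue
        p = params[roi.roi_id]
        layer = assign_layer(roi.group.centroid_px, geometry)
        cy, cx = roi.group.centroid_um(pixel_pitch)
        rows.append(
            {
                "roi_id": roi.roi_id,
                "slice_id": metadata["slice_id"],
                "genotype": metadata["genotype"],
                "sex": metadata["sex"],
                "residence_layer": layer,
                "stimulation_layer": metadata["stimulation_layer"],
                "in_analysis": layer in ANALYSIS_LAYERS,
                "amplitude_pct": p.amplitude_pct,
                "latency_ms": p.latency,
                "rise_time_ms": p.rise_time,
                "decay_time_ms": p.decay_time,
                "half_width_ms": p.half_width,
                "distance_um": p.distance,
                "dn_latency_ms_per_um": p.dn_latency,
                "n_pixels": len(roi.group.pixels),
                "area_um2": roi.group.area_um2(pixel_pitch),
                "centroid_row_um": cy,
                "centroid_col_um": cx,
                "mean_snr": roi.group.mean_snr,
            }
        )
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
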