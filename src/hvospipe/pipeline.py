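"""End-to-end orchestration: preprocess -> detect -> extract -> tabulate -> stats.

Every threshold of the run is carried in a :class:`RunConfig`, echoed into
the manifest, and the whole run is deterministic given config + seed.  The
manifest records the candidate count and the count removed by each
exclusion rule, so candidates = accepted + sum of rejections always holds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .detect import (
    ROI,
    REJECTION_REASONS,
    amplitude_outlier_exclusion,
    detect_candidates,
    direct_stimulation_exclusion,
)
from .layers import LayerGeometry, build_cell_table
from .metrics import EpspParams, ExtractionError, electrode_distance, extract_params
from .preprocess import DffMovie, preprocess
from .stats import layer_averages, report_to_frame, run_group_stats

__all__ = ["RunConfig", "analyze_slice", "run_pipeline"]


@dataclass
class RunConfig:
    """All tunable constants of a pipeline run."""

    # detection
    snr_cutoff: float = 5.0
    amp_cutoff: float | None = None  # None -> amp_cutoff_mult x median prestimulus RMS
    amp_cutoff_mult: float = 7.0
    k: int = 4
    cluster_mean_cutoff: float = 5.0
    electrode_radius_um: float = 45.0
    min_latency_ms: float = 1.0
    outlier_sd: float = 3.0
    max_extent_px: int = 3
    max_area_um2: float = 360.0
    response_window_ms: float = 50.0
    # preprocessing
    spatial_sigma: float = 1.0
    # stats
    min_n: int = 8
    bootstrap_B: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    # inputs: list of {path, slice_id, genotype, sex, stimulation_layer,
    #                  layer_boundaries: [row, row]}
    slices: list[dict] = field(default_factory=list)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def analyze_slice(
    dff: DffMovie, config: RunConfig
) -> tuple[list[ROI], dict[int, EpspParams], dict]:
    """Detection + kinetics + per-slice exclusions for one movie.

    The dataset-level amplitude-outlier rule is NOT applied here; the
    pipeline applies it once over the pooled cells of the run.
    """
    dt = dff.frame_interval
    start = int(np.ceil(dff.stim_time / dt))
    stop = min(dff.n_frames, int(np.floor((dff.stim_time + config.response_window_ms) / dt)) + 1)
    rois, diag = detect_candidates(
        dff,
        amp_cutoff=config.amp_cutoff,
        amp_cutoff_mult=config.amp_cutoff_mult,
        snr_cutoff=config.snr_cutoff,
        k=config.k,
        cluster_mean_cutoff=config.cluster_mean_cutoff,
        response_window=(start, stop),
        max_extent_px=config.max_extent_px,
        max_area_um2=config.max_area_um2,
    )
    params: dict[int, EpspParams] = {}
    latencies: dict[int, float] = {}
    for roi in rois:
        if not roi.accepted:
            continue
        try:
            p = extract_params(dff.time_axis, roi.trace, dff.stim_time, (start, stop))
        except ExtractionError:
            roi.reject("noisy_waveform")
            continue
        dist = electrode_distance(roi.group.centroid_um(dff.pixel_pitch), dff.electrode_um)
        p.distance = dist
        p.dn_latency = p.latency / dist if dist > 0 else None
        params[roi.roi_id] = p
        latencies[roi.roi_id] = p.latency
    direct_stimulation_exclusion(
        rois,
        dff.electrode_um,
        latencies,
        dff.pixel_pitch,
        min_distance_um=config.electrode_radius_um,
        min_latency_ms=config.min_latency_ms,
    )
    return rois, params, diag


def _exclusion_counts(rois: list[ROI]) -> dict[str, int]:
    counts = {reason: 0 for reason in REJECTION_REASONS if reason != "none"}
    counts["accepted"] = 0
    for roi in rois:
        if roi.accepted:
            counts["accepted"] += 1
        else:
            counts[roi.rejection_reason] += 1
    counts["candidates"] = len(rois)
    return counts


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every slice in the config and write the artifact directory.

    Outputs: ``cell_table.csv``, ``units.csv``, ``stats_report.csv``,
    ``stats_report.txt`` and ``manifest.json``.
    """
    if not config.slices:
        raise ValueError("config lists no input slices")
    out = Path(out_dir)

    per_slice = []
    for entry in config.slices:
        stack, sidecar = hio.read_scene(entry["path"])
        dff = preprocess(stack, sigma=config.spatial_sigma)
        rois, params, diag = analyze_slice(dff, config)
        geometry = LayerGeometry(boundaries=list(entry.get("layer_boundaries", [30.0, 55.0])))
        metadata = {
            "slice_id": entry["slice_id"],
            "genotype": entry["genotype"],
            "sex": entry["sex"],
            "stimulation_layer": entry["stimulation_layer"],
        }
        per_slice.append((entry, rois, params, metadata, geometry, dff.pixel_pitch, diag))

    # dataset-level single-pass amplitude outlier rule over pooled cells;
    # roi ids are offset per slice to stay unique across the run
    all_rois: list[ROI] = []
    flat_amps: dict[int, float] = {}
    offset = 0
    for _, rois, params, *_rest in per_slice:
        for roi in rois:
            old = roi.roi_id
            roi.roi_id = old + offset
            if old in params:
                params[roi.roi_id] = params.pop(old)
        flat_amps.update({rid: p.amplitude for rid, p in params.items()})
        all_rois.extend(rois)
        offset += 10_000
    amplitude_outlier_exclusion(all_rois, flat_amps, n_sd=config.outlier_sd)

    tables = []
    for entry, rois, params, metadata, geometry, pitch, diag in per_slice:
        tables.append(build_cell_table(rois, params, metadata, geometry, pitch))
    cell_table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()

    units = layer_averages(cell_table, min_n=config.min_n)
    stats_report = None
    if len(units) >= 3 and units["genotype"].nunique() > 1:
        try:
            report = run_group_stats(units, B=config.bootstrap_B, seed=config.seed, alpha=config.alpha)
            stats_report = report_to_frame(report)
        except ValueError:
            stats_report = None  # too few units for the full design

    out.mkdir(parents=True, exist_ok=True)
    cell_table.to_csv(out / "cell_table.csv", index=False)
    units.to_csv(out / "units.csv", index=False)
    if stats_report is not None:
        stats_report.to_csv(out / "stats_report.csv", index=False)
        (out / "stats_report.txt").write_text(stats_report.to_string(index=False) + "\n")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_slices": len(per_slice),
        "exclusion_counts": _exclusion_counts(all_rois),
        "n_units": int(len(units)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
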