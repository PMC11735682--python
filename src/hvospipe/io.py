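"""File formats: multi-page TIFF movies + JSON sidecars, npz dF/F bundles.

A simulated scene directory holds one multi-page TIFF per trial
(``trial_000.tif`` ...), the resting-light image, and ``scene.json``
with the scene configuration and ground truth.  Real recordings follow
the same layout minus the ground-truth block.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .preprocess import DffMovie, TrialStack
from .simulate import GroundTruth, SceneConfig, SynthCell

__all__ = ["write_scene", "read_scene", "write_dff", "read_dff"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_scene(
    out_dir: str | Path,
    stack: TrialStack,
    config: SceneConfig | None = None,
    truth: GroundTruth | None = None,
    metadata: dict | None = None,
) -> Path:
    """Write trial TIFFs plus a JSON sidecar; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(stack.n_trials):
        tifffile.imwrite(out / f"trial_{i:03d}.tif", stack.data[i].astype(np.float32))
    tifffile.imwrite(out / "resting_light.tif", stack.resting_light.astype(np.float32))
    sidecar = {
        "frame_interval": stack.frame_interval,
        "stim_time": stack.stim_time,
        "electrode_um": list(stack.electrode_um),
        "pixel_pitch": stack.pixel_pitch,
        "n_trials": stack.n_trials,
        "metadata": _jsonable({**stack.metadata, **(metadata or {})}),
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        sidecar["scene_config"] = _jsonable(cfg)
    if truth is not None:
        sidecar["ground_truth"] = {
            "cells": [_jsonable(dataclasses.asdict(c)) for c in truth.cells],
            "latencies": truth.latencies.tolist(),
            "masks": [np.argwhere(m).tolist() for m in truth.masks],
        }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_scene(scene_dir: str | Path) -> tuple[TrialStack, dict]:
    """Load a scene directory back into a TrialStack plus its sidecar dict."""
    scene_dir = Path(scene_dir)
    sidecar_path = scene_dir / "scene.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no scene.json in {scene_dir}")
    sidecar = json.loads(sidecar_path.read_text())
    trials = sorted(scene_dir.glob("trial_*.tif"))
    if not trials:
        raise FileNotFoundError(f"no trial TIFFs in {scene_dir}")
    data = np.stack([tifffile.imread(t).astype(float) for t in trials])
    rl = tifffile.imread(scene_dir / "resting_light.tif").astype(float)
    stack = TrialStack(
        data=data,
        frame_interval=sidecar["frame_interval"],
        stim_time=sidecar["stim_time"],
        resting_light=rl,
        electrode_um=tuple(sidecar["electrode_um"]),
        pixel_pitch=sidecar["pixel_pitch"],
        metadata=sidecar.get("metadata", {}),
    )
    return stack, sidecar


def write_dff(path: str | Path, movie: DffMovie) -> Path:
    """dF/F movie as .npz with a JSON provenance sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=movie.data,
        excluded=movie.excluded_pixels if movie.excluded_pixels is not None else np.zeros((0,)),
    )
    meta = {
        "frame_interval": movie.frame_interval,
        "stim_time": movie.stim_time,
        "baseline_window": list(movie.baseline_window),
        "filter_provenance": movie.filter_provenance,
        "electrode_um": list(movie.electrode_um),
        "pixel_pitch": movie.pixel_pitch,
        "metadata": _jsonable(movie.metadata),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_dff(path: str | Path) -> DffMovie:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    arrs = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    excl = arrs["excluded"]
    return DffMovie(
        data=arrs["data"],
        frame_interval=meta["frame_interval"],
        stim_time=meta["stim_time"],
        baseline_window=tuple(meta["baseline_window"]),
        filter_provenance=list(meta["filter_provenance"]),
        excluded_pixels=excl.astype(bool) if excl.size else None,
        electrode_um=tuple(meta["electrode_um"]),
        pixel_pitch=meta["pixel_pitch"],
        metadata=meta.get("metadata", {}),
    )
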