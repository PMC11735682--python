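"""From raw trial stacks to the filtered dF/F movie.

Processing order is fixed: trial average -> dF/F -> sigma=1 spatial
Gaussian -> nine-point binomial temporal filter.  Every step has unit DC
gain (constants map to themselves) and is recorded in the movie's
provenance so downstream stages can assert the order.

The dF/F baseline B is the per-pixel mean over a prestimulus window
(default: stim - 20 ms up to stim - 2 ms); the resting-light image is
kept for noise calibration and display but is not the divisor, so the
prestimulus mean is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TrialStack",
    "DffMovie",
    "BINOMIAL9",
    "average_trials",
    "compute_dff",
    "spatial_filter",
    "temporal_filter_binomial9",
    "baseline_rms",
    "baseline_rms_map",
    "default_baseline_window",
    "preprocess",
]

#: nine-point binomial kernel (row 8 of Pascal's triangle, normalized)
BINOMIAL9 = np.array([1, 8, 28, 56, 70, 56, 28, 8, 1], dtype=float) / 256.0


@dataclass
class TrialStack:
    """Raw multi-trial fluorescence movie plus acquisition metadata."""

    data: np.ndarray  # (n_trials, n_frames, H, W) counts
    frame_interval: float  # ms (0.5 at 2000 frames/s)
    stim_time: float  # ms
    resting_light: np.ndarray  # (H, W), strictly positive where analyzed
    electrode_um: tuple[float, float] = (0.0, 0.0)  # (row, col) um
    pixel_pitch: float = 19.0 / 3.0  # um / pixel
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("TrialStack.data must be (n_trials, n_frames, H, W)")
        if self.n_frames * self.frame_interval <= self.stim_time:
            raise ValueError("record does not cover stim_time")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class DffMovie:
    """Fractional fluorescence change movie and its filter provenance."""

    data: np.ndarray  # (n_frames, H, W), unitless
    frame_interval: float
    stim_time: float
    baseline_window: tuple[int, int]  # [start, stop) frame indices
    filter_provenance: list[str] = field(default_factory=list)
    excluded_pixels: np.ndarray | None = None  # True where baseline <= 0
    resting_light: np.ndarray | None = None
    electrode_um: tuple[float, float] = (0.0, 0.0)
    pixel_pitch: float = 19.0 / 3.0
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def average_trials(stack: TrialStack) -> TrialStack:
    """Pointwise mean across trials (the recordings' five-trial average)."""
    if stack.n_trials < 1:
        raise ValueError("need at least one trial")
    mean = stack.data.mean(axis=0, keepdims=True)
    out = TrialStack(
        data=mean,
        frame_interval=stack.frame_interval,
        stim_time=stack.stim_time,
        resting_light=stack.resting_light,
        electrode_um=stack.electrode_um,
        pixel_pitch=stack.pixel_pitch,
        metadata=dict(stack.metadata),
    )
    out.metadata["n_trials_averaged"] = stack.n_trials
    return out


def default_baseline_window(stack_or_movie) -> tuple[int, int]:
    """Frames from stim - 20 ms up to stim - 2 ms (clipped to the record)."""
    dt = stack_or_movie.frame_interval
    stim = stack_or_movie.stim_time
    start = max(0, int(np.ceil((stim - 20.0) / dt)))
    stop = int(np.floor((stim - 2.0) / dt)) + 1
    if stop <= start:
        raise ValueError("record too short for the default prestimulus baseline window")
    return start, stop


def compute_dff(stack: TrialStack, baseline_window: tuple[int, int] | None = None) -> DffMovie:
    """Per-pixel dF/F(t) = (F(t) - B) / B with B the prestimulus mean.

    Pixels with non-positive baseline are flagged in ``excluded_pixels``
    and carry zero signal (they are excluded from all analysis).
    """
    if stack.n_trials != 1:
        raise ValueError("compute_dff expects a trial-averaged (single-trial) stack")
    movie = stack.data[0]
    if baseline_window is None:
        baseline_window = default_baseline_window(stack)
    start, stop = baseline_window
    if not (0 <= start < stop <= stack.n_frames):
        raise ValueError(f"invalid baseline window {baseline_window}")
    if stop * stack.frame_interval > stack.stim_time:
        raise ValueError("baseline window must be entirely prestimulus")
    b = movie[start:stop].mean(axis=0)
    bad = b <= 0
    b_safe = np.where(bad, 1.0, b)
    dff = (movie - b_safe[None, :, :]) / b_safe[None, :, :]
    dff[:, bad] = 0.0
    return DffMovie(
        data=dff,
        frame_interval=stack.frame_interval,
        stim_time=stack.stim_time,
        baseline_window=(start, stop),
        filter_provenance=["average_trials", "dff"],
        excluded_pixels=bad,
        resting_light=stack.resting_light,
        electrode_um=stack.electrode_um,
        pixel_pitch=stack.pixel_pitch,
        metadata=dict(stack.metadata),
    )


def spatial_filter(movie: DffMovie, sigma: float = 1.0) -> DffMovie:
    """Per-frame 2-D Gaussian smoothing (sigma in pixels, reflect edges)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        data = movie.data.copy()
    else:
        data = gaussian_filter(movie.data, sigma=(0.0, sigma, sigma), mode="reflect")
    out = _with_data(movie, data)
    out.filter_provenance.append(f"spatial_gaussian_sigma={sigma:g}")
    return out


def temporal_filter_binomial9(x: np.ndarray | DffMovie) -> np.ndarray | DffMovie:
    """Convolve along time with the 9-point binomial kernel, reflect edges.

    Accepts a 1-D trace or a DffMovie (time on axis 0).
    """
    if isinstance(x, DffMovie):
        out = _with_data(x, _binomial9_axis0(x.data))
        out.filter_provenance.append("temporal_binomial9")
        return out
    return _binomial9_axis0(np.asarray(x, dtype=float))


def _binomial9_axis0(arr: np.ndarray) -> np.ndarray:
    if arr.shape[0] < 9:
        raise ValueError("need at least 9 samples for the binomial-9 filter")
    padded = np.pad(arr, [(4, 4)] + [(0, 0)] * (arr.ndim - 1), mode="reflect")
    out = np.zeros_like(arr, dtype=float)
    for i, w in enumerate(BINOMIAL9):
        out += w * padded[i : i + arr.shape[0]]
    return out


def _with_data(movie: DffMovie, data: np.ndarray) -> DffMovie:
    return DffMovie(
        data=data,
        frame_interval=movie.frame_interval,
        stim_time=movie.stim_time,
        baseline_window=movie.baseline_window,
        filter_provenance=list(movie.filter_provenance),
        excluded_pixels=movie.excluded_pixels,
        resting_light=movie.resting_light,
        electrode_um=movie.electrode_um,
        pixel_pitch=movie.pixel_pitch,
        metadata=dict(movie.metadata),
    )


def baseline_rms(trace: np.ndarray, baseline_window: tuple[int, int]) -> float:
    """RMS of the zero-meaned prestimulus segment of a (filtered) trace."""
    start, stop = baseline_window
    seg = np.asarray(trace, dtype=float)[start:stop]
    if seg.size < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    return float(np.sqrt(np.mean((seg - seg.mean()) ** 2)))


def baseline_rms_map(movie: DffMovie) -> np.ndarray:
    start, stop = movie.baseline_window
    seg = movie.data[start:stop]
    return np.sqrt(np.mean((seg - seg.mean(axis=0, keepdims=True)) ** 2, axis=0))


def preprocess(
    stack: TrialStack,
    sigma: float = 1.0,
    baseline_window: tuple[int, int] | None = None,
) -> DffMovie:
    """Full preprocessing chain: average -> dF/F -> spatial -> temporal."""
    averaged = average_trials(stack)
    dff = compute_dff(averaged, baseline_window)
    dff = spatial_filter(dff, sigma=sigma)
    dff = temporal_filter_binomial9(dff)
    return dff
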