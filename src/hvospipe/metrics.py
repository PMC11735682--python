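"""EPSP parameter extraction from ROI-averaged dF/F traces.

Five kinetic parameters per cell, all defined from the peak and the two
half-maximum crossings of the negative-going optical EPSP:

* amplitude   — magnitude of the peak dF/F decrease (reported as % dF/F)
* latency     — stimulus to *leading* half-maximum crossing
* rise-time   — leading half-maximum crossing to peak
* decay-time  — peak to *trailing* half-maximum crossing
* half-width  — time between the two half-maximum crossings
                (== rise-time + decay-time exactly, by construction)

plus distance-normalized latency (latency / electrode distance, ms/um),
which removes the axonal-conduction component that grows linearly with
distance from the stimulation site.

Half-maximum crossing times are located by linear interpolation between
the two samples bracketing half of the peak value; the peak is the global
negative extremum inside the response window (robust to slow after-waves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EpspParams",
    "ExtractionError",
    "extract_params",
    "distance_normalized_latency",
    "electrode_distance",
]


class ExtractionError(RuntimeError):
    """Raised when a trace has no analyzable EPSP (the noisy-waveform case)."""


@dataclass
class EpspParams:
    amplitude: float  # |dF/F| at the peak, unitless (fraction, not %)
    latency: float  # ms
    rise_time: float  # ms
    decay_time: float  # ms
    half_width: float  # ms
    distance: float | None = None  # um from stimulating electrode
    dn_latency: float | None = None  # ms / um

    @property
    def amplitude_pct(self) -> float:
        return 100.0 * self.amplitude


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    # linear interpolation of the time where the trace crosses `level`
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def extract_params(
    time_ms: np.ndarray,
    trace: np.ndarray,
    stim_time: float,
    response_window: tuple[int, int] | None = None,
) -> EpspParams:
    """Extract the five kinetic parameters from one trace.

    ``response_window`` is a [start, stop) frame-index window in which the
    peak is sought (default: from the stimulus to the end of the record).
    Raises :class:`ExtractionError` when the trace has no negative-going
    peak or when a half-maximum crossing cannot be found in the record
    (e.g. a truncated decay).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if time_ms.shape != trace.shape:
        raise ValueError("time and trace must have the same shape")
    if response_window is None:
        start = int(np.searchsorted(time_ms, stim_time))
        stop = trace.size
    else:
        start, stop = response_window
    if not (0 <= start < stop <= trace.size):
        raise ValueError(f"invalid response window ({start}, {stop})")

    seg = trace[start:stop]
    peak_rel = int(np.argmin(seg))
    peak_idx = start + peak_rel
    peak_val = trace[peak_idx]
    if peak_val >= 0:
        raise ExtractionError("no negative-going deflection in the response window")
    half = peak_val / 2.0
    t_peak = time_ms[peak_idx]

    # leading crossing: walk backward from the peak
    lead = None
    for i in range(peak_idx - 1, -1, -1):
        if trace[i] > half >= trace[i + 1]:
            lead = _interp_crossing(time_ms[i], time_ms[i + 1], trace[i], trace[i + 1], half)
            break
    if lead is None:
        raise ExtractionError("no leading half-maximum crossing found")

    # trailing crossing: walk forward from the peak
    trail = None
    for i in range(peak_idx, trace.size - 1):
        if trace[i] <= half < trace[i + 1]:
            trail = _interp_crossing(time_ms[i], time_ms[i + 1], trace[i], trace[i + 1], half)
            break
    if trail is None:
        raise ExtractionError("no trailing half-maximum crossing within the record")

    latency = lead - stim_time
    return EpspParams(
        amplitude=float(-peak_val),
        latency=float(latency),
        rise_time=float(t_peak - lead),
        decay_time=float(trail - t_peak),
        half_width=float(trail - lead),
    )


def distance_normalized_latency(latency_ms: float, distance_um: float) -> float:
    """Latency divided by electrode distance, ms/um."""
    if distance_um <= 0:
        raise ValueError("distance must be positive")
    return latency_ms / distance_um


def electrode_distance(
    centroid_um: tuple[float, float], electrode_um: tuple[float, float]
) -> float:
    """Euclidean distance between two points given in um."""
    return float(np.hypot(centroid_um[0] - electrode_um[0], centroid_um[1] - electrode_um[1]))
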