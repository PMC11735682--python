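"""Dual-exponential EPSP waveform model.

The optical EPSP reported by a hybrid voltage sensor is a transient
*decrease* in fluorescence (depolarization quenches emission), so traces
here are negative-going.  The shape is the standard minimal synaptic
waveform, a difference of exponentials

    w(t) = exp(-(t - t0)/tau_decay) - exp(-(t - t0)/tau_rise),   t >= t0

normalized so that the peak magnitude equals the requested amplitude.
"""

from __future__ import annotations

import numpy as np

__all__ = ["epsp_peak_time", "make_epsp_waveform"]


def _validate_taus(tau_rise: float, tau_decay: float) -> None:
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError(f"time constants must be positive, got tau_rise={tau_rise}, tau_decay={tau_decay}")
    if tau_rise >= tau_decay:
        raise ValueError(f"tau_rise must be < tau_decay, got {tau_rise} >= {tau_decay}")


def epsp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time from onset to the peak of the difference-of-exponentials, in the
    units of the time constants."""
    _validate_taus(tau_rise, tau_decay)
    return (tau_rise * tau_decay) / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def make_epsp_waveform(
    amplitude: float,
    tau_rise: float,
    tau_decay: float,
    onset_time: float,
    time_axis: np.ndarray,
) -> np.ndarray:
    """Render a negative-going EPSP on ``time_axis``.

    Parameters
    ----------
    amplitude
        Peak fractional fluorescence *decrease* (>= 0, unitless dF/F).
    tau_rise, tau_decay
        Rise and decay time constants, same units as ``time_axis``;
        ``tau_rise < tau_decay``.
    onset_time
        Response onset; the trace is identically zero before it.
    time_axis
        Sample times (must bracket ``onset_time``).

    Returns
    -------
    trace with ``min(trace) == -amplitude`` (up to sampling of the peak)
    and zeros before onset.
    """
    _validate_taus(tau_rise, tau_decay)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0 (magnitude of the fluorescence decrease)")
    time_axis = np.asarray(time_axis, dtype=float)
    if not (time_axis[0] <= onset_time <= time_axis[-1]):
        raise ValueError(f"onset_time={onset_time} outside time axis [{time_axis[0]}, {time_axis[-1]}]")
    s = time_axis - onset_time
    w = np.where(s > 0, np.exp(-np.clip(s, 0, None) / tau_decay) - np.exp(-np.clip(s, 0, None) / tau_rise), 0.0)
    t_star = epsp_peak_time(tau_rise, tau_decay)
    peak = np.exp(-t_star / tau_decay) - np.exp(-t_star / tau_rise)  # analytic maximum of w
    return -amplitude * w / peak
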