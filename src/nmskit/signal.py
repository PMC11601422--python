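"""Gait-cycle signal processing: variable-cutoff filtering and resampling.

Motion and ground-reaction channels are low-pass filtered at a cutoff that
scales inversely with the cycle period tf (cutoff = k/tf Hz, k = 7 for motion
data and 3.5 for EMG envelopes), using a fourth-order zero-phase-lag
Butterworth filter, and cycles are resampled onto a fixed grid (101 points by
convention) so that trials of different durations are comparable.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, interp1d

__all__ = ["variable_cutoff_filter", "zero_phase_lowpass", "resample_cycle",
           "interp_series", "CYCLE_POINTS"]

CYCLE_POINTS = 101  # standard per-cycle grid


def zero_phase_lowpass(values: np.ndarray, cutoff_hz: float, fs: float,
                       order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    ``order`` is the order of the underlying one-pass filter; the
    forward-backward application squares its magnitude response.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cutoff_hz:g} Hz is at or above Nyquist {nyq:g} Hz")
    sos = sps.butter(order, cutoff_hz / nyq, btype="low", output="sos")
    padlen = min(len(values) - 1, 3 * 2 * order * 2)
    return sps.sosfiltfilt(sos, np.asarray(values, float), padlen=padlen)


def variable_cutoff_filter(values: np.ndarray, time: np.ndarray,
                           k: float = 7.0, tf: float | None = None,
                           order: int = 4) -> np.ndarray:
    """Low-pass at k/tf Hz where tf is the cycle period (defaults to the
    span of ``time``). Requires uniform sampling."""
    time = np.asarray(time, float)
    dt = np.diff(time)
    if len(dt) == 0:
        return np.asarray(values, float).copy()
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("variable_cutoff_filter requires uniform sampling")
    if tf is None:
        tf = time[-1] - time[0]
    return zero_phase_lowpass(values, k / tf, 1.0 / dt[0], order=order)


def resample_cycle(time: np.ndarray, values: np.ndarray,
                   n: int = CYCLE_POINTS) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate onto ``n`` evenly spaced points spanning the time range.

    Endpoints are preserved exactly. Cubic interpolation when at least four
    samples are available, linear otherwise.
    """
    if n < 2:
        raise ValueError("resample_cycle requires n >= 2")
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    new_time = np.linspace(time[0], time[-1], n)
    out = interp_series(time, values, new_time)
    # guarantee bit-exact endpoints
    out[..., 0] = np.moveaxis(values, 0, -1)[..., 0]
    out[..., -1] = np.moveaxis(values, 0, -1)[..., -1]
    return new_time, np.moveaxis(out, -1, 0)


def interp_series(time: np.ndarray, values: np.ndarray,
                  new_time: np.ndarray) -> np.ndarray:
    """Interpolate along the first axis; returns values with time as the
    LAST axis (convenient for broadcasting)."""
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    if len(time) >= 4:
        f = CubicSpline(time, values, axis=0)
    else:
        f = interp1d(time, values, axis=0, kind="linear",
                     fill_value="extrapolate")
    return np.moveaxis(f(np.asarray(new_time, float)), 0, -1)
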