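"""EMG-driven Hill-type muscle-tendon model with a rigid tendon.

The signal path per muscle is

    raw EMG -> envelope -> delay & scale -> activation dynamics ->
    activation nonlinearity -> Hill force (with fiber kinematics from the
    rigid-tendon assumption) -> joint moments via moment arms.

Curve shapes are fixed (only their length/force parameters are calibrated):
the active force-length curve is a Gaussian with peak 1 at normalized length
1 and width 0.45; the force-velocity curve is a Hill hyperbola with
f_V(0) = 1, f_V(-1) = 0 and an eccentric plateau of 1.4; the passive curve is
exponential with f_P(1) = 0 and f_P(1.6) = 1. Maximum shortening velocity is
fixed at 10 optimal fiber lengths per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal import zero_phase_lowpass, interp_series
from .tables import TimeSeriesTable, DataError
from scipy import signal as sps

__all__ = [
    "MuscleTendonParams", "EmgSettings", "process_emg", "delay_and_scale",
    "activation_dynamics", "inverse_activation_dynamics",
    "activation_nonlinearity", "inverse_activation_nonlinearity",
    "rigid_tendon_state", "muscle_tendon_force", "muscle_joint_moments",
    "active_force_length", "force_velocity", "passive_force_length",
    "V_MAX_NORM",
]

V_MAX_NORM = 10.0          # maximum contraction velocity, optimal lengths / s
FL_WIDTH = 0.45            # Gaussian active force-length width
FV_ECC_PLATEAU = 1.4       # eccentric force-velocity asymptote
FP_REF_LENGTH = 1.6        # normalized length where passive force = F_max


@dataclass
class MuscleTendonParams:
    """Per-muscle Hill-model and activation-dynamics parameters."""

    optimal_fiber_length: float = 0.10          # m
    tendon_slack_length: float = 0.20           # m
    max_isometric_force: float = 1000.0         # N
    pennation_at_optimal: float = 0.0           # rad
    emg_scale: float = 1.0                      # (0, 1]
    electromechanical_delay: float = 0.0        # s, [0, 0.2]
    activation_time_constant: float = 0.015     # s
    deactivation_time_constant: float = 0.060   # s
    activation_nonlinearity: float = 0.0        # A in [-3, 0]; 0 = linear

    def __post_init__(self):
        if self.optimal_fiber_length <= 0 or self.tendon_slack_length <= 0:
            raise ValueError("muscle lengths must be positive")
        if self.max_isometric_force <= 0:
            raise ValueError("max isometric force must be positive")
        if not 0 <= self.pennation_at_optimal < np.pi / 2:
            raise ValueError("pennation must be in [0, pi/2)")
        if not 0 < self.emg_scale <= 1:
            raise ValueError("EMG scale must be in (0, 1]")
        if not 0 <= self.electromechanical_delay <= 0.2:
            raise ValueError("electromechanical delay must be in [0, 0.2] s")
        if (self.activation_time_constant <= 0
                or self.deactivation_time_constant <= 0):
            raise ValueError("time constants must be positive")

    def replace(self, **kw) -> "MuscleTendonParams":
        return replace(self, **kw)


@dataclass
class EmgSettings:
    """EMG processing protocol: 40 Hz high-pass, demean, rectify, low-pass
    at 3.5/tf Hz, normalize by the per-channel max over all provided cycles,
    then offset so the channel minimum is zero. Envelopes are padded with
    0.2 s before the cycle start to leave room for electromechanical delay
    (18 points on the standard 101-point grid of a ~1.1 s cycle)."""

    highpass_hz: float = 40.0
    lowpass_numerator: float = 3.5       # cutoff = 3.5 / tf Hz
    pad_duration: float = 0.2            # s
    filter_order: int = 4


def process_emg(raw: TimeSeriesTable, tf: float,
                settings: EmgSettings | None = None
                ) -> tuple[TimeSeriesTable, list[str]]:
    """Process raw EMG channels into normalized envelopes in [0, 1].

    Returns the envelope table plus the list of channels flagged all-zero
    (returned as zeros rather than raising).
    """
    settings = settings or EmgSettings()
    t = raw.time
    dt = np.diff(t)
    fs = 1.0 / dt[0]
    if settings.highpass_hz >= fs / 2:
        raise ValueError("sampling rate too low for the 40 Hz high-pass")
    sos = sps.butter(settings.filter_order,
                     settings.highpass_hz / (fs / 2), btype="high",
                     output="sos")
    flagged = []
    cols = {}
    for name in raw.names:
        x = raw[name]
        if np.allclose(x, 0.0):
            flagged.append(name)
            cols[name] = np.zeros_like(x)
            continue
        hp = sps.sosfiltfilt(sos, x)
        hp = hp - hp.mean()
        rect = np.abs(hp)
        env = zero_phase_lowpass(rect, settings.lowpass_numerator / tf, fs,
                                 order=settings.filter_order)
        env = np.clip(env, 0.0, None)
        peak = env.max()
        if peak <= 1e-10 * max(1.0, float(np.abs(x).max())):
            flagged.append(name)
            cols[name] = np.zeros_like(x)
            continue
        env = env / peak            # max over all provided cycles -> 1
        env = env - env.min()       # offset so the channel minimum is 0
        if env.max() > 0:           # restore a unit peak after the offset
            env = env / env.max()
        cols[name] = env
    return TimeSeriesTable(t, cols, dict(raw.metadata)), flagged


def delay_and_scale(time: np.ndarray, envelope: np.ndarray, delay: float,
                    scale: float, pad_duration: float = 0.2) -> np.ndarray:
    """Excitation e(t) = scale * env(t - delay) on the cycle grid.

    The envelope is assumed to cover [t0 - pad_duration, t_end]; samples
    before t0 beyond the available pad are an error.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    if delay > pad_duration:
        raise ValueError(
            f"delay {delay:g} s exceeds the available {pad_duration:g} s pad")
    time = np.asarray(time, float)
    shifted = interp_series(time, np.asarray(envelope, float), time - delay)
    return scale * shifted


def activation_dynamics(time: np.ndarray, excitation: np.ndarray,
                        params: MuscleTendonParams) -> np.ndarray:
    """First-order bilinear activation dynamics, backward-Euler discretized.

    adot = (e - a) / tau with tau = tau_act when e > a (activation) else
    tau_deact; a(0) = e(0).
    """
    e = np.asarray(excitation, float)
    if not np.all(np.isfinite(e)):
        raise DataError("non-finite excitation")
    t = np.asarray(time, float)
    a = np.empty_like(e)
    a[0] = e[0]
    for k in range(1, len(e)):
        h = t[k] - t[k - 1]
        # backward Euler: a_k = (a_{k-1} + h e_k / tau) / (1 + h / tau)
        tau = (params.activation_time_constant
               if e[k] > a[k - 1] else params.deactivation_time_constant)
        a[k] = (a[k - 1] + h * e[k] / tau) / (1.0 + h / tau)
    return a


def inverse_activation_dynamics(time: np.ndarray, activation: np.ndarray,
                                params: MuscleTendonParams) -> np.ndarray:
    """Excitation that reproduces ``activation`` under the backward-Euler
    discretization (used by the synthetic-data generator)."""
    a = np.asarray(activation, float)
    t = np.asarray(time, float)
    e = np.empty_like(a)
    e[0] = a[0]
    for k in range(1, len(a)):
        h = t[k] - t[k - 1]
        # invert assuming the activation branch, check consistency, else
        # use the deactivation branch
        for tau in (params.activation_time_constant,
                    params.deactivation_time_constant):
            ek = (a[k] * (1.0 + h / tau) - a[k - 1]) * tau / h
            if (tau == params.activation_time_constant) == (ek > a[k - 1]):
                break
        e[k] = ek
    return e


def activation_nonlinearity(a, A: float):
    """a_nl = (exp(A a) - 1) / (exp(A) - 1); the A -> 0 limit is identity."""
    a = np.asarray(a, float)
    if abs(A) < 1e-8:
        return a.copy()
    return np.expm1(A * a) / np.expm1(A)


def inverse_activation_nonlinearity(a_nl, A: float):
    a_nl = np.asarray(a_nl, float)
    if abs(A) < 1e-8:
        return a_nl.copy()
    return np.log1p(a_nl * np.expm1(A)) / A


def active_force_length(lnorm):
    return np.exp(-((np.asarray(lnorm, float) - 1.0) / FL_WIDTH) ** 2)


def force_velocity(vnorm):
    """Hill hyperbola: f(0) = 1, f(-1) = 0, eccentric plateau 1.4.

    Concentric (v < 0): f = (1 + v) / (1 - v / a_f) with a_f = 0.25.
    Eccentric (v > 0): smooth saturation towards the plateau with matched
    slope at v = 0.
    """
    v = np.asarray(vnorm, float)
    a_f = 0.25
    conc = (1.0 + np.clip(v, -1.0, 0.0)) / (1.0 - np.clip(v, -1.0, 0.0) / a_f)
    slope0 = 1.0 + 1.0 / a_f  # df/dv at 0- of the concentric branch
    ecc = FV_ECC_PLATEAU - (FV_ECC_PLATEAU - 1.0) * np.exp(
        -slope0 * np.clip(v, 0.0, None) / (FV_ECC_PLATEAU - 1.0))
    return np.where(v < 0, conc, ecc)


def passive_force_length(lnorm):
    """Exponential passive curve, zero at/below optimal length and equal to
    1 (i.e. F_max) at normalized length 1.6."""
    l = np.asarray(lnorm, float)
    k = 5.0
    raw = np.expm1(k * np.clip(l - 1.0, 0.0, None))
    return raw / np.expm1(k * (FP_REF_LENGTH - 1.0))


def rigid_tendon_state(l_mt, v_mt, params: MuscleTendonParams):
    """Fiber kinematics under the rigid-tendon, constant-thickness pennation
    assumption.

    Returns (normalized fiber length, normalized fiber velocity,
    cos(pennation), clamped-sample mask).
    """
    l_mt = np.asarray(l_mt, float)
    v_mt = np.asarray(v_mt, float)
    l_opt = params.optimal_fiber_length
    l_ts = params.tendon_slack_length
    guard = l_ts - 0.5 * l_opt
    clamped = l_mt <= guard
    l_eff = np.where(clamped, guard + 1e-9, l_mt)
    h = l_opt * np.sin(params.pennation_at_optimal)   # constant thickness
    fiber = np.sqrt((l_eff - l_ts) ** 2 + h ** 2)
    cos_penn = np.clip((l_eff - l_ts) / fiber, 1e-6, 1.0)
    lnorm = fiber / l_opt
    vnorm = v_mt * cos_penn / (V_MAX_NORM * l_opt)
    return lnorm, vnorm, cos_penn, clamped


def muscle_tendon_force(a_nl, lnorm, vnorm, cos_penn,
                        params: MuscleTendonParams):
    """Tendon force and its passive component (N) from fiber state."""
    a_nl = np.asarray(a_nl, float)
    active = a_nl * active_force_length(lnorm) * force_velocity(vnorm)
    passive = passive_force_length(lnorm)
    F = params.max_isometric_force * (active + passive) * cos_penn
    F_passive = params.max_isometric_force * passive * cos_penn
    return F, F_passive


def muscle_joint_moments(model, Q, forces: dict[str, np.ndarray],
                         coordinates: list[str] | None = None
                         ) -> dict[str, np.ndarray]:
    """Net muscle moment per coordinate: sum_i r_ij(q) F_i."""
    Q = np.asarray(Q, float)
    coords = coordinates or model.coordinate_names
    out = {}
    for cname in coords:
        total = np.zeros(Q.shape[1:] if Q.ndim > 1 else ())
        for mname, F in forces.items():
            r = model.muscle_moment_arm(mname, cname, Q)
            total = total + r * np.asarray(F, float)
        out[cname] = total
    return out
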