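"""Standardized cost-term formulation shared by every tool.

Each term is ((value - error_center) / max_allowable_error)^2: a deviation
equal to its maximum allowable error contributes exactly 1, larger deviations
are amplified (1.1^2 = 1.21) and smaller ones attenuated (0.9^2 = 0.81), which
lets heterogeneous quantities (moments, activations, forces) be summed on a
physically meaningful common scale. Time-varying terms are additionally
normalized by the trial duration so trials of different lengths contribute
equally.
"""

from __future__ import annotations

import numpy as np

__all__ = ["standardized_cost", "continuous_term", "term_residuals"]


def standardized_cost(value, center, max_allowable):
    """((value - center) / max_allowable)^2, elementwise."""
    if np.any(np.asarray(max_allowable) <= 0):
        raise ValueError("maximum allowable error must be positive")
    return ((np.asarray(value, float) - center) / max_allowable) ** 2


def continuous_term(time, values, center, max_allowable,
                    duration: float | None = None) -> float:
    """Time-normalized integral of the standardized cost of a trajectory:
    (1/T) * int ((v(t) - c) / e)^2 dt, trapezoidal."""
    time = np.asarray(time, float)
    T = (time[-1] - time[0]) if duration is None else duration
    if T <= 0:
        raise ValueError("duration must be positive")
    integrand = standardized_cost(values, center, max_allowable)
    return float(np.trapezoid(integrand, time) / T)


def term_residuals(time, values, center, max_allowable,
                   duration: float | None = None) -> np.ndarray:
    """Least-squares residual vector whose sum of squares equals
    :func:`continuous_term` (trapezoidal quadrature weights folded in)."""
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    T = (time[-1] - time[0]) if duration is None else duration
    w = np.zeros(len(time))
    dt = np.diff(time)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return np.sqrt(w / T) * (values - center) / max_allowable
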