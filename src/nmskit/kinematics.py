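"""Marker-based inverse kinematics.

Per frame, coordinates are found by damped nonlinear least squares on the
weighted model-to-experimental marker distance residuals, seeded from the
previous frame's solution (frame 0 from zeros, or a caller-supplied seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import Model, segment_kinematics
from .tables import MarkerData, TimeSeriesTable

__all__ = ["inverse_kinematics", "IkResult", "IkError"]


class IkError(ValueError):
    """IK configuration error (e.g. no shared markers)."""


@dataclass
class IkResult:
    coordinates: TimeSeriesTable
    rms_error: np.ndarray                 # per-frame RMS marker error, m
    max_error: np.ndarray                 # per-frame max marker error, m
    flagged_frames: list[int] = field(default_factory=list)

    @property
    def overall_rms(self) -> float:
        return float(np.sqrt(np.mean(self.rms_error ** 2)))


def _marker_residual_fn(model: Model, names, weights):
    locs = [(model.markers[n].segment, model.markers[n].location[:2])
            for n in names]
    w = np.sqrt(np.repeat(weights, 2))

    def residual(q, targets_xy):
        kin = segment_kinematics(model, np.asarray(q, float)[:, None])
        res = np.empty(2 * len(locs))
        for i, (seg, loc) in enumerate(locs):
            p, _, _ = kin[seg].point(loc)
            res[2 * i: 2 * i + 2] = p[:, 0] - targets_xy[i]
        return w * res

    return residual


def inverse_kinematics(model: Model, markers: MarkerData,
                       weights: dict[str, float] | None = None,
                       seed: np.ndarray | None = None,
                       tol: float = 1e-12) -> IkResult:
    """Solve IK for every frame of ``markers``.

    Marker weights default to 1. Out-of-plane (z) marker components are
    ignored by the planar model. Non-converged frames are flagged in the
    diagnostics but their best iterates are still returned.
    """
    shared = [n for n in markers.names if n in model.markers]
    if not shared:
        raise IkError("no markers shared between model and data")
    wvec = np.array([1.0 if weights is None else weights.get(n, 1.0)
                     for n in shared])
    if np.any(wvec < 0):
        raise IkError("marker weights must be non-negative")
    residual = _marker_residual_fn(model, shared, wvec)
    n = model.n_coordinates
    F = len(markers)
    Q = np.zeros((n, F))
    rms = np.zeros(F)
    mx = np.zeros(F)
    flagged = []
    q = np.zeros(n) if seed is None else np.asarray(seed, float).copy()
    for f in range(F):
        targets = [markers.markers[nm][f, :2] for nm in shared]
        sol = least_squares(residual, q, args=(targets,), method="lm"
                            if 2 * len(shared) >= n else "trf",
                            xtol=tol, ftol=tol, gtol=tol)
        if not sol.success:
            flagged.append(f)
        q = sol.x
        Q[:, f] = q
        dists = np.linalg.norm(
            (sol.fun / np.sqrt(np.repeat(np.maximum(wvec, 1e-300), 2))
             ).reshape(-1, 2), axis=1)
        rms[f] = np.sqrt(np.mean(dists ** 2))
        mx[f] = dists.max()
    table = TimeSeriesTable(markers.time,
                            {c: Q[j] for j, c in
                             enumerate(model.coordinate_names)})
    return IkResult(table, rms, mx, flagged)
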