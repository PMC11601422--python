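"""Joint Model Personalization (JMP).

Optimizes joint frame locations/orientations, uniform body scale factors,
and marker local-position offsets so that inverse kinematics reproduces
experimental marker data as closely as possible. The cost is the sum of
squared marker distance errors normalized by trial duration and marker count,
with IK re-solved at every candidate parameter set (nested formulation). A
run is an ordered list of tasks, each with its own marker data and design
variables, each starting from the previous task's model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinematics import inverse_kinematics
from .model import Model, marker_positions
from .tables import MarkerData, TimeSeriesTable

__all__ = ["JmpTask", "JointModelPersonalizer", "jmp_cost", "check_rom",
           "RomWarning", "ROM_WARN_DEG"]

ROM_WARN_DEG = 25.0


class RomWarning(UserWarning):
    """A personalized coordinate moves through insufficient range of motion."""


@dataclass
class JmpTask:
    """One JMP task: marker data plus the design variables to optimize.

    joint_parameters: list of (joint, frame in {'parent','child'},
    kind in {'location','orientation'}); locations optimize planar x/y
    offsets, orientations the frame angle.
    """
    markers: MarkerData
    joint_parameters: list[tuple[str, str, str]] = field(default_factory=list)
    scale_segments: list[str] = field(default_factory=list)
    marker_offsets: list[str] = field(default_factory=list)
    marker_offset_bound: float = 0.030      # m
    location_bound: float = 0.05            # m
    orientation_bound: float = np.deg2rad(20.0)
    scale_bounds: tuple[float, float] = (0.7, 1.3)
    rom_coordinates: list[str] = field(default_factory=list)
    marker_weights: dict[str, float] | None = None

    def validate(self, model: Model) -> None:
        if not (self.joint_parameters or self.scale_segments
                or self.marker_offsets):
            raise ValueError("JMP task selects no design variables")
        joint_names = {j.name for j in model.joints}
        for jname, frame, kind in self.joint_parameters:
            if jname not in joint_names:
                raise ValueError(f"unknown joint {jname!r}")
            if frame not in ("parent", "child") or kind not in (
                    "location", "orientation"):
                raise ValueError(f"bad joint parameter spec {frame}/{kind}")
        for s in self.scale_segments:
            if s not in model.segments:
                raise ValueError(f"unknown segment {s!r}")
        for m in self.marker_offsets:
            if m not in model.markers:
                raise ValueError(f"unknown marker {m!r}")


def _frame_weights(time: np.ndarray) -> np.ndarray:
    """Per-frame dt quadrature weights (each frame carries its dt share)."""
    w = np.zeros(len(time))
    if len(time) == 1:
        return np.ones(1)
    dt = np.diff(time)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return w


def jmp_cost(model: Model, markers: MarkerData,
             weights: dict[str, float] | None = None) -> float:
    """(1/(T M)) sum_f dt_f sum_m ||p_model - p_exp||^2 with IK re-solved."""
    res = _marker_error_residuals(model, markers, weights)
    return float(np.sum(res ** 2))


def _marker_error_residuals(model: Model, markers: MarkerData,
                            weights=None) -> np.ndarray:
    ik = inverse_kinematics(model, markers, weights=weights)
    shared = [n for n in markers.names if n in model.markers]
    Q = ik.coordinates.as_matrix(model.coordinate_names).T
    pos = marker_positions(model, Q)
    T = markers.time[-1] - markers.time[0]
    if T <= 0:
        T = 1.0
    wf = _frame_weights(markers.time)
    M = len(shared)
    res = []
    for nm in shared:
        err = pos[nm][:, :2] - markers.markers[nm][:, :2]   # (F, 2)
        res.append(np.sqrt(wf / (T * M))[:, None] * err)
    return np.concatenate([r.ravel() for r in res])


def check_rom(coordinates: TimeSeriesTable, names: list[str]
              ) -> list[str]:
    """Warn for every coordinate whose range of motion is below ~25 degrees
    (strictly less). Returns the warning messages."""
    msgs = []
    for c in names:
        rom = np.ptp(coordinates[c])
        if np.rad2deg(rom) < ROM_WARN_DEG:
            msg = (f"coordinate {c!r} moves through only "
                   f"{np.rad2deg(rom):.1f} deg (< {ROM_WARN_DEG:g} deg); "
                   "joint personalization may be unreliable")
            warnings.warn(msg, RomWarning, stacklevel=2)
            msgs.append(msg)
    return msgs


class JointModelPersonalizer:
    """Runs an ordered list of :class:`JmpTask` and exposes the personalized
    model plus per-task marker-error diagnostics.

    Attributes set by :meth:`fit` (trailing underscore):

    model_
        the personalized model after all tasks.
    diagnostics_
        per task: pre/post cost and pre/post RMS / max marker distance
        errors (m).
    """

    def __init__(self, tasks: list[JmpTask], max_nfev: int = 200):
        self.tasks = tasks
        self.max_nfev = max_nfev

    # -- design-vector plumbing ---------------------------------------------
    @staticmethod
    def _pack(task: JmpTask):
        names, lo, hi = [], [], []
        for jname, frame, kind in task.joint_parameters:
            if kind == "location":
                for ax in ("x", "y"):
                    names.append(("joint", jname, frame, "location", ax))
                    lo.append(-task.location_bound)
                    hi.append(task.location_bound)
            else:
                names.append(("joint", jname, frame, "orientation", None))
                lo.append(-task.orientation_bound)
                hi.append(task.orientation_bound)
        for s in task.scale_segments:
            names.append(("scale", s, None, None, None))
            lo.append(task.scale_bounds[0] - 1.0)
            hi.append(task.scale_bounds[1] - 1.0)
        for m in task.marker_offsets:
            for ax in ("x", "y"):
                names.append(("marker", m, None, None, ax))
                lo.append(-task.marker_offset_bound)
                hi.append(task.marker_offset_bound)
        return names, np.array(lo), np.array(hi)

    @staticmethod
    def _apply(base: Model, names, x) -> Model:
        model = base.copy()
        joints = {j.name: j for j in model.joints}
        for (kind, name, frame, param, ax), v in zip(names, x):
            if kind == "joint":
                j = joints[name]
                if param == "location":
                    attr = f"location_in_{frame}"
                    loc = getattr(j, attr).copy()
                    loc[0 if ax == "x" else 1] += v
                    setattr(j, attr, loc)
                else:
                    attr = f"orientation_in_{frame}"
                    setattr(j, attr, getattr(j, attr) + v)
            elif kind == "scale":
                model.scale_segment(name, 1.0 + v)
            else:
                mk = model.markers[name]
                loc = mk.location.copy()
                loc[0 if ax == "x" else 1] += v
                mk.location = loc
        return model

    # -- fitting -------------------------------------------------------------
    def fit(self, model: Model) -> "JointModelPersonalizer":
        current = model.copy()
        self.diagnostics_ = []
        self.task_parameters_ = []
        for k, task in enumerate(self.tasks):
            task.validate(current)
            names, lo, hi = self._pack(task)
            base = current

            def residuals(x):
                cand = self._apply(base, names, x)
                return _marker_error_residuals(cand, task.markers,
                                               task.marker_weights)

            pre_res = residuals(np.zeros(len(names)))
            pre_cost = float(np.sum(pre_res ** 2))
            sol = least_squares(residuals, np.zeros(len(names)),
                                bounds=(lo, hi), method="trf",
                                diff_step=1e-4, max_nfev=self.max_nfev)
            post_cost = float(np.sum(sol.fun ** 2))
            if post_cost <= pre_cost:
                current = self._apply(base, names, sol.x)
                x_used = sol.x
            else:   # optimizer failed to improve; keep the starting model
                x_used = np.zeros(len(names))
                post_cost = pre_cost
            self.task_parameters_.append(dict(zip(
                ["/".join(str(p) for p in nm if p is not None)
                 for nm in names], x_used)))
            diag = {
                "task": k,
                "pre_cost": pre_cost, "post_cost": post_cost,
                **self._marker_stats(base, task, "pre"),
                **self._marker_stats(current, task, "post"),
            }
            ik = inverse_kinematics(current, task.markers,
                                    task.marker_weights)
            diag["rom_warnings"] = check_rom(ik.coordinates,
                                             task.rom_coordinates)
            self.diagnostics_.append(diag)
        self.model_ = current
        return self

    @staticmethod
    def _marker_stats(model: Model, task: JmpTask, tag: str) -> dict:
        ik = inverse_kinematics(model, task.markers, task.marker_weights)
        return {f"{tag}_rms_m": float(np.sqrt(np.mean(ik.rms_error ** 2))),
                f"{tag}_max_m": float(np.max(ik.max_error))}
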