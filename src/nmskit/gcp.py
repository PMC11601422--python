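"""Ground Contact Personalization (GCP).

An elastic-foundation foot-ground contact model: a uniform grid of point
springs attached to a two-segment foot (hindfoot + toes connected by an
oblique pin), with per-spring stiffness and shared damping, friction and
resting-length parameters. Calibration runs staged nonlinear least squares
matching vertical GRF, then horizontal GRF, then ground reaction moments,
each stage warm-starting from the previous solution, optionally with
B-spline kinematic deviations from the experimental foot motion.

Ground reaction moments are compared about the time-varying projection of a
midfoot superior marker onto the ground, which keeps moment magnitudes small
and well scaled throughout stance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import least_squares

from .costs import term_residuals
from .model import GROUND, Model, ModelError, segment_kinematics
from .tables import TimeSeriesTable, DataError

__all__ = [
    "ContactModel", "FootModel", "extract_foot", "contact_wrench",
    "wrench_from_kinematics",
    "shift_moment_point", "bspline_node_count", "deviation_spline",
    "GcpTask", "GroundContactPersonalizer",
]


@dataclass
class ContactModel:
    """Spring-grid contact parameters.

    stations: one (segment, local_xy) per spring, grid stored row-major
    (rows x cols). Stiffness is per spring; damping, friction coefficients
    and resting length are shared by all springs.
    """
    rows: int = 5
    cols: int = 11
    stiffness: np.ndarray = None                    # N/m, (rows*cols,)
    stations: list[tuple[str, np.ndarray]] = field(default_factory=list)
    damping: float = 1.0                            # s/m
    viscous_friction: float = 0.5
    dynamic_friction: float = 0.0                   # off by default
    resting_length: float = 0.0                     # m
    smoothing: float = 1e-3                         # m, contact-onset width
    transition_velocity: float = 0.05               # m/s, tanh regularization

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        n = self.rows * self.cols
        if self.stiffness is None:
            self.stiffness = np.full(n, 1e4)
        self.stiffness = np.asarray(self.stiffness, float)
        if self.stiffness.shape != (n,):
            raise ValueError(f"expected {n} stiffness values")
        if np.any(self.stiffness < 0):
            raise ValueError("stiffnesses must be >= 0")
        if self.stations and len(self.stations) != n:
            raise ValueError("one station per spring required")

    def neighbor_pairs(self) -> list[tuple[int, int]]:
        """4-connected grid neighbor index pairs (row-major layout)."""
        pairs = []
        for r in range(self.rows):
            for c in range(self.cols):
                i = r * self.cols + c
                if c + 1 < self.cols:
                    pairs.append((i, i + 1))
                if r + 1 < self.rows:
                    pairs.append((i, i + self.cols))
        return pairs

    def copy(self) -> "ContactModel":
        import copy
        return copy.deepcopy(self)


@dataclass
class FootModel:
    """Two-segment foot extracted from a full-body model: hindfoot attached
    to ground by a planar root joint plus the original toe pin."""
    model: Model
    hindfoot: str
    toes: str
    root_coordinates: list[str]
    toe_coordinate: str

    @property
    def coordinate_names(self) -> list[str]:
        return self.model.coordinate_names


def extract_foot(model: Model, hindfoot: str, toes: str,
                 Q: np.ndarray | None = None
                 ) -> tuple[FootModel, np.ndarray | None]:
    """Extract a standalone foot model and hindfoot-to-ground coordinates
    consistent with full-body coordinates ``Q`` (n_coords, F).

    The returned coordinate array (4, F) is ordered (tx, ty, rz, toe angle);
    forward kinematics of the extracted model under these coordinates
    reproduces the original foot segment poses exactly.
    """
    if hindfoot not in model.segments:
        raise ModelError(f"no hindfoot segment {hindfoot!r}")
    if toes not in model.segments:
        raise ModelError(f"no toes segment {toes!r}")
    toe_joint = next((j for j in model.joints
                      if j.parent == hindfoot and j.child == toes), None)
    if toe_joint is None:
        raise ModelError(f"no joint connects {hindfoot!r} to {toes!r}")
    foot = Model()
    for name in (hindfoot, toes):
        s = model.segments[name]
        foot.add_segment(name, s.mass, s.inertia, s.com)
    root_names = [f"{hindfoot}_tx", f"{hindfoot}_ty", f"{hindfoot}_rz"]
    foot.add_joint(f"{hindfoot}_ground", "planar_root_3dof", GROUND,
                   hindfoot, coordinate_names=root_names)
    foot.add_joint(toe_joint.name, toe_joint.joint_type, hindfoot, toes,
                   location_in_parent=toe_joint.location_in_parent,
                   orientation_in_parent=toe_joint.orientation_in_parent,
                   location_in_child=toe_joint.location_in_child,
                   orientation_in_child=toe_joint.orientation_in_child,
                   axis=toe_joint.axis,
                   coordinate_names=list(toe_joint.coordinates))
    for mk in model.markers.values():
        if mk.segment in (hindfoot, toes):
            foot.add_marker(mk.name, mk.segment, mk.location)
    foot.validate()
    fm = FootModel(foot, hindfoot, toes, root_names,
                   toe_joint.coordinates[0])
    if Q is None:
        return fm, None
    Q = np.atleast_2d(np.asarray(Q, float))
    kin = segment_kinematics(model, Q)
    hp = kin[hindfoot]
    toe_idx = model.coordinate_index(toe_joint.coordinates[0])
    Qf = np.vstack([hp.o[0], hp.o[1], hp.phi, Q[toe_idx]])
    return fm, Qf


def contact_wrench(foot: FootModel, contact: ContactModel, Q, V=None,
                   expression_point=None):
    """Total contact force (2, F), z-moment (F,) about ``expression_point``
    (2, F) or the origin, plus per-spring diagnostics.

    Per spring: penetration d = resting_length - height, smoothed spring
    deflection s(d) (C^1, compactly supported: 0 below -h, (d + h)^2 / 4h
    inside the smoothing band, exactly d above +h); normal force
    k s(d) (1 + c v_pen) clamped at zero (v_pen is the downward penetration
    rate); tangential force -f_n (mu_d tanh(v_slip / v_t) + mu_v v_slip).

    ``foot`` may be a :class:`FootModel` or any :class:`Model` containing
    the station segments.
    """
    model = getattr(foot, "model", foot)
    Q = np.atleast_2d(np.asarray(Q, float))
    V = np.zeros_like(Q) if V is None else np.atleast_2d(np.asarray(V, float))
    kin = segment_kinematics(model, Q, V)
    return wrench_from_kinematics(contact, kin, expression_point)


def wrench_from_kinematics(contact: ContactModel, kin, expression_point=None):
    """Contact wrench from precomputed segment kinematics."""
    some = next(iter(kin.values()))
    F = some.phi.shape[0]
    total = np.zeros((2, F))
    mz = np.zeros(F)
    P = (np.zeros((2, F)) if expression_point is None
         else np.broadcast_to(np.asarray(expression_point, float),
                              (2, F)))
    per_spring = []
    h = contact.smoothing
    for k_i, (seg, loc) in zip(contact.stiffness, contact.stations):
        p, pd, _ = kin[seg].point(np.asarray(loc, float))
        pen = contact.resting_length - p[1]
        s = _smooth_deflection(pen, h)
        v_pen = -pd[1]
        fn = k_i * s * np.clip(1.0 + contact.damping * v_pen, 0.0, None)
        v_slip = pd[0]
        ft = -fn * (contact.dynamic_friction
                    * np.tanh(v_slip / contact.transition_velocity)
                    + contact.viscous_friction * v_slip)
        total[0] += ft
        total[1] += fn
        mz += (p[0] - P[0]) * fn - (p[1] - P[1]) * ft
        per_spring.append({"segment": seg, "normal": fn, "tangential": ft,
                           "position": p})
    return total, mz, per_spring


def _smooth_deflection(pen, h):
    """C^1 contact-onset smoothing with compact support: zero at or below
    -h, quadratic blend (pen + h)^2 / 4h on (-h, h), exactly pen above h.
    A spring farther than h from the ground produces exactly zero force."""
    pen = np.asarray(pen, float)
    return np.where(pen >= h, pen,
                    np.where(pen <= -h, 0.0,
                             (pen + h) ** 2 / (4.0 * h)))


def shift_moment_point(force, moment, p_old, p_new):
    """Re-express a moment about a new point: M_new = M + (p_old - p_new) x F.

    Accepts 3-vectors (or arrays of them, last axis 3)."""
    force = np.asarray(force, float)
    moment = np.asarray(moment, float)
    shift = np.asarray(p_old, float) - np.asarray(p_new, float)
    return moment + np.cross(shift, force)


def bspline_node_count(duration: float, cutoff_hz: float) -> int:
    """Number of B-spline nodes resolving content up to ``cutoff_hz`` over
    ``duration``: max(5, ceil(duration * cutoff) + 4); a cubic spline needs
    at least degree + 2 nodes."""
    if duration <= 0 or cutoff_hz <= 0:
        raise ValueError("duration and cutoff must be positive")
    return max(5, int(np.ceil(duration * cutoff_hz)) + 4)


def deviation_spline(time, nodes, degree: int = 3) -> np.ndarray:
    """Evaluate a deviation curve from uniformly spaced interior nodes over
    the span of ``time`` (clamped cubic B-spline)."""
    time = np.asarray(time, float)
    nodes = np.asarray(nodes, float)
    n = len(nodes)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} nodes")
    t0, t1 = time[0], time[-1]
    interior = np.linspace(t0, t1, n - degree + 1)[1:-1]
    knots = np.concatenate([[t0] * (degree + 1), interior,
                            [t1] * (degree + 1)])
    return BSpline(knots, nodes, degree)(time)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class GcpTask:
    """One calibration stage: which residual groups are in the cost and
    which shared parameters are free."""
    track_vertical: bool = True
    track_horizontal: bool = False
    track_moment: bool = False
    free_stiffness: bool = True
    free_damping: bool = False
    free_viscous_friction: bool = False
    free_dynamic_friction: bool = False
    free_resting_length: bool = True
    free_deviations: bool = False
    max_nfev: int = 60


DEFAULT_ALLOWABLE = {
    "vertical_force": 10.0,       # N
    "horizontal_force": 5.0,      # N
    "moment": 2.0,                # N*m
    "neighbor": 2e4,              # N/m stiffness difference
    "marker": 0.005,              # m
    "marker_velocity": 0.05,      # m/s
    "rotation": np.deg2rad(3.0),
    "translation": 0.010,         # m
}


class GroundContactPersonalizer:
    """Staged calibration of a :class:`ContactModel` against ground
    reactions for one foot (or two feet sharing parameters when
    ``symmetric``).

    Parameters
    ----------
    foot, contact:
        extracted foot model and initial contact model.
    tasks:
        ordered calibration stages (defaults to the three-stage protocol:
        vertical GRF; + horizontal GRF; + ground reaction moments).
    allowable:
        per-group maximum allowable errors for the standardized cost.

    Fitted attributes: ``contact_`` (calibrated model), ``deviations_``
    (per-coordinate B-spline nodes), ``diagnostics_`` (per-stage force /
    moment / kinematic RMS errors).
    """

    def __init__(self, foot: FootModel, contact: ContactModel,
                 tasks: list[GcpTask] | None = None,
                 allowable: dict | None = None,
                 deviation_cutoff_hz: float = 7.0,
                 stiffness_bounds=(0.0, 1e6)):
        self.foot = foot
        self.contact = contact
        self.tasks = tasks or [
            GcpTask(track_vertical=True),
            GcpTask(track_vertical=True, track_horizontal=True,
                    free_viscous_friction=True),
            GcpTask(track_vertical=True, track_horizontal=True,
                    track_moment=True, free_viscous_friction=True),
        ]
        self.allowable = {**DEFAULT_ALLOWABLE, **(allowable or {})}
        self.deviation_cutoff_hz = deviation_cutoff_hz
        self.stiffness_bounds = stiffness_bounds

    # -- design vector -------------------------------------------------------
    def _pack(self, task: GcpTask, contact: ContactModel, dev_nodes):
        x, lo, hi, tags = [], [], [], []

        def add(vals, lo_v, hi_v, tag):
            vals = np.atleast_1d(np.asarray(vals, float))
            x.extend(vals)
            lo.extend([lo_v] * len(vals))
            hi.extend([hi_v] * len(vals))
            tags.append((tag, len(vals)))

        if task.free_stiffness:
            add(contact.stiffness, *self.stiffness_bounds, "stiffness")
        if task.free_damping:
            add(contact.damping, 0.0, 10.0, "damping")
        if task.free_viscous_friction:
            add(contact.viscous_friction, 0.0, 10.0, "viscous")
        if task.free_dynamic_friction:
            add(contact.dynamic_friction, 0.0, 2.0, "dynamic")
        if task.free_resting_length:
            add(contact.resting_length, -0.05, 0.05, "resting")
        if task.free_deviations:
            for cname, nodes in dev_nodes.items():
                bound = (self.allowable["rotation"]
                         if self.foot.model.coordinates[cname].kind
                         == "rotational" else self.allowable["translation"])
                add(nodes, -bound, bound, f"dev:{cname}")
        return (np.array(x), np.array(lo), np.array(hi), tags)

    def _unpack(self, x, tags, contact: ContactModel, dev_nodes):
        contact = contact.copy()
        dev = {k: v.copy() for k, v in dev_nodes.items()}
        i = 0
        for tag, n in tags:
            chunk = x[i:i + n]
            i += n
            if tag == "stiffness":
                contact.stiffness = chunk.copy()
            elif tag == "damping":
                contact.damping = float(chunk[0])
            elif tag == "viscous":
                contact.viscous_friction = float(chunk[0])
            elif tag == "dynamic":
                contact.dynamic_friction = float(chunk[0])
            elif tag == "resting":
                contact.resting_length = float(chunk[0])
            elif tag.startswith("dev:"):
                dev[tag[4:]] = chunk.copy()
        return contact, dev

    # -- residuals -----------------------------------------------------------
    def _trajectories(self, time, Q_exp, dev):
        Q = Q_exp.copy()
        for cname, nodes in dev.items():
            j = self.foot.model.coordinate_index(cname)
            Q[j] = Q[j] + deviation_spline(time, nodes)
        from scipy.interpolate import CubicSpline
        V = CubicSpline(time, Q.T)(time, 1).T
        return Q, V

    def _residuals(self, task, time, Q_exp, grf_force, grf_moment, point,
                   contact, dev):
        Q, V = self._trajectories(time, Q_exp, dev)
        force, mz, _ = contact_wrench(self.foot, contact, Q, V,
                                      expression_point=point)
        res = []
        if task.track_vertical:
            res.append(term_residuals(time, force[1] - grf_force[1], 0.0,
                                      self.allowable["vertical_force"]))
        if task.track_horizontal:
            res.append(term_residuals(time, force[0] - grf_force[0], 0.0,
                                      self.allowable["horizontal_force"]))
        if task.track_moment:
            res.append(term_residuals(time, mz - grf_moment, 0.0,
                                      self.allowable["moment"]))
        pairs = contact.neighbor_pairs()
        if pairs and task.free_stiffness:
            k = contact.stiffness
            diffs = np.array([k[i] - k[j] for i, j in pairs])
            res.append(diffs / (self.allowable["neighbor"]
                                * np.sqrt(len(pairs))))
        if task.free_deviations:
            for cname, nodes in dev.items():
                j = self.foot.model.coordinate_index(cname)
                kind = self.foot.model.coordinates[cname].kind
                allow = (self.allowable["rotation"] if kind == "rotational"
                         else self.allowable["translation"])
                res.append(term_residuals(time, Q[j] - Q_exp[j], 0.0, allow))
        return np.concatenate(res)

    # -- fit -----------------------------------------------------------------
    def fit(self, time, Q_exp, grf_force, grf_moment, grf_point,
            midfoot_x=None) -> "GroundContactPersonalizer":
        """Calibrate against experimental data on a stance window.

        time (F,); Q_exp (4, F) experimental foot coordinates; grf_force
        (2, F); grf_moment (F,) with its expression point grf_point (2, F);
        midfoot_x (F,): ground projection (x) of the midfoot superior
        marker, used as the common moment expression point (defaults to the
        hindfoot origin x).
        """
        time = np.asarray(time, float)
        Q_exp = np.asarray(Q_exp, float)
        if Q_exp.shape[1] != len(time) or np.asarray(grf_force).shape[1] != \
                len(time):
            raise DataError("kinematics and ground reaction tables must "
                            "share the same time increments")
        if midfoot_x is None:
            midfoot_x = Q_exp[0]
        point = np.vstack([np.asarray(midfoot_x, float),
                           np.zeros(len(time))])
        # re-express experimental moments about the midfoot projection
        f3 = np.column_stack([grf_force[0], grf_force[1],
                              np.zeros(len(time))])
        m3 = np.column_stack([np.zeros((len(time), 2)), grf_moment])
        gp = np.asarray(grf_point, float)
        p_old3 = np.column_stack([gp[0], gp[1], np.zeros(len(time))])
        p_new3 = np.column_stack([point[0], point[1], np.zeros(len(time))])
        m_shift = shift_moment_point(f3, m3, p_old3, p_new3)[:, 2]

        contact = self.contact.copy()
        n_nodes = bspline_node_count(time[-1] - time[0],
                                     self.deviation_cutoff_hz)
        dev = {c: np.zeros(n_nodes) for c in self.foot.coordinate_names}
        self.diagnostics_ = []
        for stage, task in enumerate(self.tasks):
            x0, lo, hi, tags = self._pack(task, contact, dev)

            def fun(x):
                cand, cdev = self._unpack(x, tags, contact, dev)
                return self._residuals(task, time, Q_exp, grf_force,
                                       m_shift, point, cand, cdev)

            sol = least_squares(fun, np.clip(x0, lo, hi), bounds=(lo, hi),
                                method="trf", x_scale="jac",
                                max_nfev=task.max_nfev)
            contact, dev = self._unpack(sol.x, tags, contact, dev)
            Q, V = self._trajectories(time, Q_exp, dev)
            force, mz, _ = contact_wrench(self.foot, contact, Q, V,
                                          expression_point=point)
            self.diagnostics_.append({
                "stage": stage,
                "vertical_rmse_N": float(np.sqrt(np.mean(
                    (force[1] - grf_force[1]) ** 2))),
                "horizontal_rmse_N": float(np.sqrt(np.mean(
                    (force[0] - grf_force[0]) ** 2))),
                "moment_rmse_Nm": float(np.sqrt(np.mean((mz - m_shift) ** 2))),
                "cost": float(np.sum(sol.fun ** 2)),
            })
        self.contact_ = contact
        self.deviations_ = dev
        return self
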