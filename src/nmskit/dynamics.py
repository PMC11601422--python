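"""Planar multibody inverse and forward dynamics.

Inverse dynamics projects exact Newton-Euler body forces onto the coordinate
directions with geometric Jacobians (d'Alembert's principle):

    tau_j = sum_b [ m_b (a_b - g) . J_bj  +  I_b phidd_b jphi_bj ] - Q_ext,j

where a_b is the COM acceleration from the closed-form pose propagation in
:mod:`nmskit.model` and Q_ext is the generalized force of any external
wrenches (ground reactions) applied at their expression points. The mass
matrix for forward dynamics is assembled from the same Jacobians
(M = sum m J^T J + I jphi^T jphi), so the inverse-dynamics / forward-dynamics
round trip is consistent by construction.

Generalized forces at a ground-attached root joint are the residual loads:
they vanish only when the motion and the applied external loads are
dynamically consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GROUND, Model, segment_kinematics, _rot
from .tables import GroundReactionData, TimeSeriesTable, DataError

__all__ = ["ExternalWrench", "inverse_dynamics", "inverse_dynamics_traj",
           "forward_dynamics", "mass_matrix", "root_coordinates",
           "grf_to_wrenches", "GRAVITY"]

GRAVITY = np.array([0.0, -9.81])


@dataclass
class ExternalWrench:
    """External load on a segment: planar force (2, F), z-moment (F,), and
    the world point (2, F) the moment is expressed about."""
    segment: str
    force: np.ndarray
    moment_z: np.ndarray
    point: np.ndarray


def root_coordinates(model: Model) -> list[str]:
    """Names of coordinates of ground-attached root joints (the residual
    load directions)."""
    out = []
    for j in model.joints:
        if j.parent == GROUND and j.joint_type in ("planar_root_3dof",
                                                   "free_root_6dof"):
            out.extend(j.coordinates)
    return out


def _body_tables(model: Model):
    segs = list(model.segments.values())
    return segs


def _jacobian_sweep(model: Model, Q, com_points, ext_points, eps=1e-6,
                    coord_indices=None):
    """One central-difference sweep over coordinates giving, per segment,
    the orientation Jacobian and, per requested point, the position Jacobian.

    com_points: list of (segment, local_xy (2,) ) for COMs.
    ext_points: list of (segment, local_xy (2, F)) for external points.
    coord_indices restricts the sweep to selected coordinates (other columns
    stay zero), which restricts which generalized-force components are valid.
    Returns (Jcom (nb, 2, n, F), Jphi {seg: (n, F)}, Jext (ne, 2, n, F)).
    """
    Q = np.asarray(Q, float)
    n, F = Q.shape
    nb, ne = len(com_points), len(ext_points)
    Jcom = np.zeros((nb, 2, n, F))
    Jext = np.zeros((ne, 2, n, F))
    Jphi = {s: np.zeros((n, F)) for s in model.segments}
    for j in (range(n) if coord_indices is None else coord_indices):
        Qp, Qm = Q.copy(), Q.copy()
        Qp[j] += eps
        Qm[j] -= eps
        kp = segment_kinematics(model, Qp)
        km = segment_kinematics(model, Qm)
        for s in model.segments:
            Jphi[s][j] = (kp[s].phi - km[s].phi) / (2 * eps)
        for i, (seg, loc) in enumerate(com_points):
            pp, _, _ = kp[seg].point(loc)
            pm, _, _ = km[seg].point(loc)
            Jcom[i, :, j, :] = (pp - pm) / (2 * eps)
        for i, (seg, loc) in enumerate(ext_points):
            pp, _, _ = kp[seg].point(loc)
            pm, _, _ = km[seg].point(loc)
            Jext[i, :, j, :] = (pp - pm) / (2 * eps)
    return Jcom, Jphi, Jext


def _ext_local_points(model: Model, kin, external):
    """Convert world expression points to per-frame segment-local coords."""
    pts = []
    for w in external:
        mp = kin[w.segment]
        rel = np.asarray(w.point, float) - mp.o
        local = _rot(-mp.phi, rel)
        pts.append((w.segment, local))
    return pts


def inverse_dynamics_raw(model: Model, Q, V, A, external=None,
                         gravity=GRAVITY, coord_indices=None, kin=None):
    """Generalized loads (n, F) for coordinate trajectories (n, F).

    ``coord_indices`` restricts computation to selected load components
    (other rows are returned as zero); ``kin`` may supply precomputed
    segment kinematics for the same Q, V, A.
    """
    Q = np.atleast_2d(np.asarray(Q, float))
    V = np.atleast_2d(np.asarray(V, float))
    A = np.atleast_2d(np.asarray(A, float))
    external = external or []
    if kin is None:
        kin = segment_kinematics(model, Q, V, A)
    segs = _body_tables(model)
    com_points = [(s.name, s.com[:2]) for s in segs]
    ext_points = _ext_local_points(model, kin, external)
    Jcom, Jphi, Jext = _jacobian_sweep(model, Q, com_points, ext_points,
                                       coord_indices=coord_indices)
    n, F = Q.shape
    tau = np.zeros((n, F))
    g = np.asarray(gravity, float)[:, None]
    for i, s in enumerate(segs):
        _, _, pdd = kin[s.name].point(s.com[:2])
        f_inertial = s.mass * (pdd - g)                     # (2, F)
        tau += np.einsum("ajf,af->jf", Jcom[i], f_inertial)
        tau += s.inertia * kin[s.name].phidd[None, :] * Jphi[s.name]
    for i, w in enumerate(external):
        tau -= np.einsum("ajf,af->jf", Jext[i], np.asarray(w.force, float))
        tau -= np.asarray(w.moment_z, float)[None, :] * Jphi[w.segment]
    return tau


def mass_matrix(model: Model, Q):
    """Joint-space mass matrix M(q), shape (F, n, n)."""
    Q = np.atleast_2d(np.asarray(Q, float))
    segs = _body_tables(model)
    com_points = [(s.name, s.com[:2]) for s in segs]
    Jcom, Jphi, _ = _jacobian_sweep(model, Q, com_points, [])
    n, F = Q.shape
    M = np.zeros((F, n, n))
    for i, s in enumerate(segs):
        J = np.moveaxis(Jcom[i], -1, 0)                     # (F, 2, n)
        M += s.mass * np.einsum("faj,fak->fjk", J, J)
        jp = Jphi[s.name].T                                 # (F, n)
        M += s.inertia * np.einsum("fj,fk->fjk", jp, jp)
    return M


def forward_dynamics(model: Model, Q, V, tau, external=None,
                     gravity=GRAVITY):
    """Coordinate accelerations from applied generalized loads."""
    Q = np.atleast_2d(np.asarray(Q, float))
    V = np.atleast_2d(np.asarray(V, float))
    tau = np.atleast_2d(np.asarray(tau, float))
    bias = inverse_dynamics_raw(model, Q, V, np.zeros_like(Q),
                                external=external, gravity=gravity)
    M = mass_matrix(model, Q)
    rhs = (tau - bias).T[..., None]                         # (F, n, 1)
    return np.linalg.solve(M, rhs)[..., 0].T                # (n, F)


def grf_to_wrenches(model: Model, grf: GroundReactionData,
                    foot_segments: dict[str, str]) -> list[ExternalWrench]:
    """Map per-foot ground reactions onto external wrenches on the named
    segments (planar: x/y force, z moment, x/y expression point)."""
    out = []
    for foot, seg in foot_segments.items():
        d = grf.feet[foot]
        out.append(ExternalWrench(
            segment=seg,
            force=d["force"][:, :2].T,
            moment_z=d["moment"][:, 2],
            point=d["point"][:, :2].T))
    return out


def inverse_dynamics(model: Model, coords: TimeSeriesTable,
                     velocities: TimeSeriesTable | None = None,
                     accelerations: TimeSeriesTable | None = None,
                     external: GroundReactionData | None = None,
                     foot_segments: dict[str, str] | None = None,
                     gravity=GRAVITY) -> TimeSeriesTable:
    """Inverse dynamics over tabulated trajectories.

    ``coords``/``velocities``/``accelerations`` must share one time vector
    and contain one column per model coordinate. Missing derivative tables
    are obtained by spline differentiation of the coordinates. The returned
    table has one generalized-load column per coordinate (moments N·m for
    rotational coordinates, forces N for translational), including the root
    residual loads.
    """
    names = model.coordinate_names
    t = coords.time
    Q = coords.as_matrix(names).T
    if velocities is not None:
        if not np.array_equal(velocities.time, t):
            raise DataError("velocity table time vector differs from "
                            "coordinates")
        V = velocities.as_matrix(names).T
    else:
        V = _spline_derivative(t, Q, 1)
    if accelerations is not None:
        if not np.array_equal(accelerations.time, t):
            raise DataError("acceleration table time vector differs from "
                            "coordinates")
        A = accelerations.as_matrix(names).T
    else:
        A = _spline_derivative(t, Q, 2)
    wrenches = []
    if external is not None:
        if not np.array_equal(external.time, t):
            raise DataError("ground reaction time vector differs from "
                            "coordinates")
        if foot_segments is None:
            raise DataError("foot_segments mapping required with external "
                            "loads")
        wrenches = grf_to_wrenches(model, external, foot_segments)
    tau = inverse_dynamics_raw(model, Q, V, A, external=wrenches,
                               gravity=gravity)
    suffix = {"rotational": "_moment", "translational": "_force"}
    cols = {name + suffix[model.coordinates[name].kind]: tau[j]
            for j, name in enumerate(names)}
    return TimeSeriesTable(t, cols, {"units": "N·m / N"})


def _spline_derivative(t, Q, order):
    from scipy.interpolate import CubicSpline
    return CubicSpline(t, Q.T)(t, order).T
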