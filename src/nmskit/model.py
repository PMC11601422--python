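"""Minimal declarative musculoskeletal model and its forward kinematics.

The model is a tree of rigid segments rooted at ``ground``, connected by
joints with parameterizable frames. Mechanics are planar (sagittal): segment
poses are an angle about z plus a 2-D origin, rotational coordinates are about
z, and translational coordinates are reserved for ground-attached root joints.
Markers carry full 3-D local positions; the out-of-plane component passes
through unchanged.

Pose kinematics are propagated with first and second time derivatives in
closed form, so downstream inverse dynamics is exact (no numerical
differentiation of positions). Muscle geometry is polynomial: each muscle
declares a moment-arm polynomial r(q) per spanned coordinate and its
muscle-tendon length follows as l_mt(q) = l_ref - sum_j int_0^{q_j} r_j(s) ds,
which keeps moment arms and lengths analytically consistent
(r_j = -d l_mt / d q_j).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Segment", "Joint", "Coordinate", "Marker", "Muscle", "Model",
    "MovingPose", "forward_kinematics", "segment_kinematics",
    "coordinate_jacobians", "point_kinematics", "ModelError",
    "read_model", "write_model",
]

GROUND = "ground"

JOINT_TYPES = ("pin", "oblique_pin", "planar_root_3dof", "free_root_6dof")


class ModelError(ValueError):
    """Model construction or reference-consistency error."""


@dataclass
class Segment:
    name: str
    mass: float = 1.0
    inertia: float = 0.01          # planar inertia about COM, kg m^2
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)


@dataclass
class Joint:
    name: str
    joint_type: str
    parent: str
    child: str
    location_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation_in_parent: float = 0.0    # rad about z
    location_in_child: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation_in_child: float = 0.0
    axis: np.ndarray = field(default_factory=lambda: np.array([0., 0., 1.]))
    coordinates: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.joint_type not in JOINT_TYPES:
            raise ModelError(f"unknown joint type {self.joint_type!r}")
        self.location_in_parent = np.asarray(self.location_in_parent, float)
        self.location_in_child = np.asarray(self.location_in_child, float)
        self.axis = np.asarray(self.axis, float)
        nrm = np.linalg.norm(self.axis)
        if nrm == 0:
            raise ModelError(f"joint {self.name}: zero axis")
        self.axis = self.axis / nrm

    @property
    def n_coordinates(self) -> int:
        return {"pin": 1, "oblique_pin": 1,
                "planar_root_3dof": 3, "free_root_6dof": 6}[self.joint_type]


@dataclass
class Coordinate:
    name: str
    kind: str                     # 'rotational' | 'translational'
    joint: str
    default_range: tuple[float, float] = (-np.pi, np.pi)


@dataclass
class Marker:
    name: str
    segment: str
    location: np.ndarray

    def __post_init__(self):
        self.location = np.asarray(self.location, float)


@dataclass
class Muscle:
    """Muscle with polynomial moment arms.

    ``moment_arms`` maps coordinate name -> ascending polynomial coefficients
    of r(q); ``ref_length`` is the muscle-tendon length at the zero pose.
    ``params`` holds the attached Hill-model parameter block (may be None
    until personalization).
    """
    name: str
    ref_length: float
    moment_arms: dict[str, np.ndarray] = field(default_factory=dict)
    params: object | None = None

    def __post_init__(self):
        self.moment_arms = {k: np.asarray(v, float)
                            for k, v in self.moment_arms.items()}


@dataclass
class Model:
    segments: dict[str, Segment] = field(default_factory=dict)
    joints: list[Joint] = field(default_factory=list)
    coordinates: dict[str, Coordinate] = field(default_factory=dict)
    markers: dict[str, Marker] = field(default_factory=dict)
    muscles: dict[str, Muscle] = field(default_factory=dict)
    muscle_groups: dict[str, list[str]] = field(default_factory=dict)
    contact: dict = field(default_factory=dict)  # foot name -> contact config

    # -- construction helpers ------------------------------------------------
    def add_segment(self, name, mass=1.0, inertia=0.01, com=(0, 0, 0)):
        if mass <= 0:
            raise ModelError(f"segment {name}: mass must be > 0")
        self.segments[name] = Segment(name, mass, inertia, np.asarray(com))
        return self.segments[name]

    def add_joint(self, name, joint_type, parent, child, *,
                  location_in_parent=(0, 0, 0), orientation_in_parent=0.0,
                  location_in_child=(0, 0, 0), orientation_in_child=0.0,
                  axis=(0, 0, 1), coordinate_names=None):
        joint = Joint(name, joint_type, parent, child,
                      np.asarray(location_in_parent), orientation_in_parent,
                      np.asarray(location_in_child), orientation_in_child,
                      np.asarray(axis))
        kinds = {"pin": ["rotational"], "oblique_pin": ["rotational"],
                 "planar_root_3dof": ["translational", "translational",
                                      "rotational"],
                 "free_root_6dof": ["translational"] * 3 + ["rotational"] * 3}
        names = coordinate_names or [f"{name}_q{i}"
                                     for i in range(joint.n_coordinates)]
        if len(names) != joint.n_coordinates:
            raise ModelError(f"joint {name}: expected "
                             f"{joint.n_coordinates} coordinate names")
        for cname, kind in zip(names, kinds[joint_type]):
            if cname in self.coordinates:
                raise ModelError(f"duplicate coordinate {cname!r}")
            rng = (-1.0, 1.0) if kind == "translational" else (-np.pi, np.pi)
            self.coordinates[cname] = Coordinate(cname, kind, name, rng)
            joint.coordinates.append(cname)
        self.joints.append(joint)
        return joint

    def add_marker(self, name, segment, location):
        if segment not in self.segments and segment != GROUND:
            raise ModelError(f"marker {name}: unknown segment {segment!r}")
        self.markers[name] = Marker(name, segment, np.asarray(location))
        return self.markers[name]

    def add_muscle(self, name, ref_length, moment_arms, params=None):
        for cname in moment_arms:
            if cname not in self.coordinates:
                raise ModelError(f"muscle {name}: unknown coordinate {cname!r}")
        self.muscles[name] = Muscle(name, ref_length,
                                    dict(moment_arms), params)
        return self.muscles[name]

    def add_muscle_group(self, name, members):
        if len(set(members)) != len(members):
            raise ModelError(f"group {name}: duplicate members")
        for m in members:
            if m not in self.muscles:
                raise ModelError(f"group {name}: unknown muscle {m!r}")
        self.muscle_groups[name] = list(members)

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        children = {}
        for j in self.joints:
            if j.parent not in self.segments and j.parent != GROUND:
                raise ModelError(f"joint {j.name}: unknown parent {j.parent!r}")
            if j.child not in self.segments:
                raise ModelError(f"joint {j.name}: unknown child {j.child!r}")
            if j.child in children:
                raise ModelError(f"segment {j.child} has two parent joints")
            children[j.child] = j
        for name, seg in self.segments.items():
            if seg.mass <= 0:
                raise ModelError(f"segment {name}: mass must be > 0")
            if name not in children:
                raise ModelError(f"segment {name} is not connected to ground")
        # tree check: walk each segment to ground, detect cycles
        for name in self.segments:
            seen, cur = set(), name
            while cur != GROUND:
                if cur in seen:
                    raise ModelError(f"cycle detected at segment {cur}")
                seen.add(cur)
                cur = children[cur].parent
        for mk in self.markers.values():
            if mk.segment not in self.segments and mk.segment != GROUND:
                raise ModelError(f"marker {mk.name}: unknown segment")
        for mu in self.muscles.values():
            for cname in mu.moment_arms:
                if cname not in self.coordinates:
                    raise ModelError(f"muscle {mu.name}: unknown coordinate "
                                     f"{cname!r}")
        for gname, members in self.muscle_groups.items():
            if len(set(members)) != len(members):
                raise ModelError(f"group {gname}: duplicate members")
            for m in members:
                if m not in self.muscles:
                    raise ModelError(f"group {gname}: unknown muscle {m!r}")

    # -- coordinate bookkeeping ---------------------------------------------
    @property
    def coordinate_names(self) -> list[str]:
        return list(self.coordinates)

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinates)

    def coordinate_index(self, name: str) -> int:
        return self.coordinate_names.index(name)

    def q_array(self, q: dict[str, float] | np.ndarray) -> np.ndarray:
        """Coerce a coordinate-value mapping (or array) to ordered array."""
        if isinstance(q, dict):
            missing = [c for c in self.coordinates if c not in q]
            if missing:
                raise ModelError(f"missing coordinate values: {missing}")
            return np.array([q[c] for c in self.coordinates], float)
        arr = np.asarray(q, float)
        if arr.shape[0] != self.n_coordinates:
            raise ModelError(f"expected {self.n_coordinates} coordinate "
                             f"values, got {arr.shape[0]}")
        return arr

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def scale_segment(self, name: str, factor: float) -> None:
        """Uniformly scale the geometry attached to one segment: its COM
        offset, its markers' local positions, and the joint-frame locations
        expressed in it (both as parent and as child)."""
        seg = self.segments[name]
        seg.com = seg.com * factor
        for mk in self.markers.values():
            if mk.segment == name:
                mk.location = mk.location * factor
        for j in self.joints:
            if j.parent == name:
                j.location_in_parent = j.location_in_parent * factor
            if j.child == name:
                j.location_in_child = j.location_in_child * factor

    # -- muscle geometry -----------------------------------------------------
    def muscle_length(self, name: str, Q: np.ndarray) -> np.ndarray:
        """Muscle-tendon length along a trajectory; Q is (n_coords, ...)."""
        mu = self.muscles[name]
        Q = np.asarray(Q, float)
        lmt = np.full(Q.shape[1:] if Q.ndim > 1 else (), mu.ref_length,
                      dtype=float)
        for cname, coeffs in mu.moment_arms.items():
            qj = Q[self.coordinate_index(cname)]
            integ = np.polynomial.polynomial.polyval(
                qj, np.concatenate([[0.0], coeffs / np.arange(1, len(coeffs) + 1)]))
            lmt = lmt - integ
        return lmt

    def muscle_moment_arm(self, name: str, cname: str,
                          Q: np.ndarray) -> np.ndarray:
        mu = self.muscles[name]
        Q = np.asarray(Q, float)
        if cname not in mu.moment_arms:
            return np.zeros(Q.shape[1:] if Q.ndim > 1 else ())
        qj = Q[self.coordinate_index(cname)]
        return np.polynomial.polynomial.polyval(qj, mu.moment_arms[cname])

    def muscle_velocity(self, name: str, Q: np.ndarray,
                        V: np.ndarray) -> np.ndarray:
        """d l_mt / dt = -sum_j r_j(q_j) qdot_j."""
        mu = self.muscles[name]
        out = 0.0
        for cname in mu.moment_arms:
            j = self.coordinate_index(cname)
            out = out - self.muscle_moment_arm(name, cname, Q) * np.asarray(V)[j]
        return out


# ---------------------------------------------------------------------------
# Pose kinematics with exact first/second time derivatives.
# ---------------------------------------------------------------------------

def _rot(phi, xy):
    """Apply planar rotation to xy (2, ...)."""
    c, s = np.cos(phi), np.sin(phi)
    return np.stack([c * xy[0] - s * xy[1], s * xy[0] + c * xy[1]])


def _perp(xy):
    """90-degree rotation S(v) = z x v."""
    return np.stack([-xy[1], xy[0]])


@dataclass
class MovingPose:
    """Planar pose (angle, origin) with first and second time derivatives."""
    phi: np.ndarray
    o: np.ndarray        # (2, ...)
    phid: np.ndarray
    od: np.ndarray
    phidd: np.ndarray
    odd: np.ndarray

    @classmethod
    def fixed(cls, phi, xy, like=None):
        z = np.zeros_like(np.asarray(phi, float) if like is None else like)
        phi = np.broadcast_to(np.asarray(phi, float), z.shape).copy()
        o = np.stack([np.broadcast_to(xy[0], z.shape),
                      np.broadcast_to(xy[1], z.shape)]).astype(float)
        return cls(phi, o, z.copy(), np.zeros_like(o),
                   z.copy(), np.zeros_like(o))

    def compose(self, other: "MovingPose") -> "MovingPose":
        R_o2 = _rot(self.phi, other.o)
        R_o2d = _rot(self.phi, other.od)
        phi = self.phi + other.phi
        o = self.o + R_o2
        phid = self.phid + other.phid
        od = self.od + self.phid * _perp(R_o2) + R_o2d
        phidd = self.phidd + other.phidd
        odd = (self.odd + self.phidd * _perp(R_o2)
               - self.phid ** 2 * R_o2
               + 2.0 * self.phid * _perp(R_o2d)
               + _rot(self.phi, other.odd))
        return MovingPose(phi, o, phid, od, phidd, odd)

    def point(self, local_xy) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World position/velocity/acceleration of a point fixed in this
        frame at planar local coordinates local_xy."""
        lx = np.stack([np.broadcast_to(local_xy[0], self.phi.shape),
                       np.broadcast_to(local_xy[1], self.phi.shape)])
        Rl = _rot(self.phi, lx)
        p = self.o + Rl
        pd = self.od + self.phid * _perp(Rl)
        pdd = (self.odd + self.phidd * _perp(Rl) - self.phid ** 2 * Rl)
        return p, pd, pdd


def _joint_motion(joint: Joint, q, v, a) -> MovingPose:
    """Pose of the joint's child frame relative to its parent frame as a
    function of its coordinates. q, v, a: (n_joint_coords, ...)."""
    if joint.joint_type in ("pin", "oblique_pin"):
        eff = joint.axis[2]  # planar projection of the rotation axis
        z2 = np.zeros((2,) + np.shape(q[0]))
        return MovingPose(q[0] * eff, z2, v[0] * eff, z2.copy(),
                          a[0] * eff, z2.copy())
    if joint.joint_type == "planar_root_3dof":
        o = np.stack([np.asarray(q[0], float), np.asarray(q[1], float)])
        od = np.stack([np.asarray(v[0], float), np.asarray(v[1], float)])
        odd = np.stack([np.asarray(a[0], float), np.asarray(a[1], float)])
        return MovingPose(np.asarray(q[2], float), o,
                          np.asarray(v[2], float), od,
                          np.asarray(a[2], float), odd)
    raise ModelError(f"joint type {joint.joint_type!r} has no planar "
                     "dynamics implementation")


def segment_kinematics(model: Model, Q, V=None, A=None
                       ) -> dict[str, MovingPose]:
    """Pose (+ derivatives) of every segment for coordinate trajectories
    Q, V, A of shape (n_coords, ...). Missing V/A are taken as zero."""
    Q = np.asarray(Q, float)
    shape = Q.shape[1:]
    V = np.zeros_like(Q) if V is None else np.asarray(V, float)
    A = np.zeros_like(Q) if A is None else np.asarray(A, float)
    like = np.zeros(shape)
    poses: dict[str, MovingPose] = {
        GROUND: MovingPose.fixed(0.0, (0.0, 0.0), like=like)}
    remaining = list(model.joints)
    while remaining:
        progressed = False
        for j in list(remaining):
            if j.parent in poses:
                idx = [model.coordinate_index(c) for c in j.coordinates]
                parent_frame = poses[j.parent].compose(
                    MovingPose.fixed(j.orientation_in_parent,
                                     j.location_in_parent[:2], like=like))
                motion = _joint_motion(j, Q[idx], V[idx], A[idx])
                child_frame = parent_frame.compose(motion)
                cth, sth = np.cos(-j.orientation_in_child), np.sin(
                    -j.orientation_in_child)
                lx, ly = -j.location_in_child[0], -j.location_in_child[1]
                inv_c = MovingPose.fixed(
                    -j.orientation_in_child,
                    (cth * lx - sth * ly, sth * lx + cth * ly), like=like)
                poses[j.child] = child_frame.compose(inv_c)
                remaining.remove(j)
                progressed = True
        if not progressed:
            raise ModelError("joint graph is not a tree rooted at ground")
    return poses


def forward_kinematics(model: Model, q) -> dict:
    """Segment poses and marker world positions at one configuration.

    Returns {'poses': {segment: (phi, origin_xy)},
             'markers': {name: world position (3,)}}.
    """
    qa = model.q_array(q)
    kin = segment_kinematics(model, qa[:, None])
    poses = {s: (mp.phi[0], mp.o[:, 0]) for s, mp in kin.items()}
    markers = {}
    for mk in model.markers.values():
        mp = kin[mk.segment]
        p, _, _ = mp.point(mk.location[:2])
        markers[mk.name] = np.array([p[0, 0], p[1, 0], mk.location[2]])
    return {"poses": poses, "markers": markers}


def marker_positions(model: Model, Q) -> dict[str, np.ndarray]:
    """Marker world trajectories for Q (n_coords, n_frames) -> (n_frames, 3)."""
    kin = segment_kinematics(model, np.asarray(Q, float))
    out = {}
    for mk in model.markers.values():
        p, _, _ = kin[mk.segment].point(mk.location[:2])
        n = p.shape[1]
        out[mk.name] = np.column_stack(
            [p[0], p[1], np.full(n, mk.location[2])])
    return out


def point_kinematics(model: Model, Q, V, A, segment: str, local_xy):
    """World position/velocity/acceleration of a segment-fixed point."""
    kin = segment_kinematics(model, Q, V, A)
    return kin[segment].point(local_xy)


def coordinate_jacobians(model: Model, Q, points: list[tuple[str, np.ndarray]],
                         eps: float = 1e-6):
    """Geometric Jacobians d p / d q for segment-fixed points, by central
    differences on the exact pose kinematics.

    Q: (n_coords, F); points: list of (segment, local_xy). Returns array
    (n_points, 2, n_coords, F).
    """
    Q = np.asarray(Q, float)
    n, F = Q.shape
    out = np.zeros((len(points), 2, n, F))
    for j in range(n):
        Qp, Qm = Q.copy(), Q.copy()
        Qp[j] += eps
        Qm[j] -= eps
        kp = segment_kinematics(model, Qp)
        km = segment_kinematics(model, Qm)
        for i, (seg, loc) in enumerate(points):
            pp, _, _ = kp[seg].point(loc)
            pm, _, _ = km[seg].point(loc)
            out[i, :, j, :] = (pp - pm) / (2 * eps)
    return out


# ---------------------------------------------------------------------------
# Model file format: a YAML key-value tree with sections
# segments/joints/coordinates/markers/muscles/groups.
# ---------------------------------------------------------------------------

def write_model(model: Model, path) -> None:
    import yaml

    doc = {
        "segments": {
            s.name: {"mass": float(s.mass), "inertia": float(s.inertia),
                     "com": [float(v) for v in s.com]}
            for s in model.segments.values()},
        "joints": [
            {"name": j.name, "type": j.joint_type, "parent": j.parent,
             "child": j.child,
             "location_in_parent": [float(v) for v in j.location_in_parent],
             "orientation_in_parent": float(j.orientation_in_parent),
             "location_in_child": [float(v) for v in j.location_in_child],
             "orientation_in_child": float(j.orientation_in_child),
             "axis": [float(v) for v in j.axis],
             "coordinates": list(j.coordinates)}
            for j in model.joints],
        "coordinates": {
            c.name: {"kind": c.kind, "joint": c.joint,
                     "range": [float(c.default_range[0]),
                               float(c.default_range[1])]}
            for c in model.coordinates.values()},
        "markers": {
            m.name: {"segment": m.segment,
                     "location": [float(v) for v in m.location]}
            for m in model.markers.values()},
        "muscles": {
            mu.name: {"ref_length": float(mu.ref_length),
                      "moment_arms": {c: [float(v) for v in coeffs]
                                      for c, coeffs in mu.moment_arms.items()}}
            for mu in model.muscles.values()},
        "groups": {g: list(members)
                   for g, members in model.muscle_groups.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path) -> Model:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = Model()
    for name, s in doc.get("segments", {}).items():
        model.add_segment(name, s["mass"], s["inertia"], s["com"])
    for j in doc.get("joints", []):
        model.add_joint(j["name"], j["type"], j["parent"], j["child"],
                        location_in_parent=j["location_in_parent"],
                        orientation_in_parent=j["orientation_in_parent"],
                        location_in_child=j["location_in_child"],
                        orientation_in_child=j["orientation_in_child"],
                        axis=j.get("axis", (0, 0, 1)),
                        coordinate_names=j["coordinates"])
    for name, c in doc.get("coordinates", {}).items():
        if name in model.coordinates:
            model.coordinates[name].default_range = tuple(c["range"])
    for name, m in doc.get("markers", {}).items():
        model.add_marker(name, m["segment"], m["location"])
    for name, mu in doc.get("muscles", {}).items():
        model.add_muscle(name, mu["ref_length"], mu["moment_arms"])
    for gname, members in doc.get("groups", {}).items():
        model.add_muscle_group(gname, members)
    model.validate()
    return model
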