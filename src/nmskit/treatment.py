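"""Treatment optimization: tracking, verification and design predictive
simulations by direct collocation.

Three tools share one problem builder ("theme and variation"):

* Tracking Optimization (TO) finds a dynamically consistent motion that
  reproduces experimental quantities (coordinates, loads, ground reactions,
  activations) as closely as their maximum allowable errors suggest.
* Verification Optimization (VO) starts from the TO solution and tracks
  only the controls (and the positions of uncontrolled coordinates),
  verifying that the controls alone reproduce the motion. A well-formulated
  VO converges quickly since its initial guess is already optimal.
* Design Optimization (DO) starts from the VO solution, adds treatment
  terms (e.g. a metabolic-cost target), static parameters with a
  model-modification hook, user-defined cost terms and optionally a free
  final time, and predicts the modified movement.

States are coordinate positions and velocities; controls are coordinate
accelerations plus torque controls and/or synergy commands (implicit
dynamics). Dynamics enter through path constraints: kinetic consistency
|ID_j - (torque_j + muscle moment_j)| <= 0.01 N*m for controlled
coordinates, root residual loads within 1 N / 0.1 N*m, plus periodicity
bounds on selected states (default 0.05 rad).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collocation import (IntegralValueCost, LinearEquality, OcpSolution,
                          PathConstraint, TrackingCost, Transcription,
                          bounds_from_range)
from .costs import standardized_cost, continuous_term
from .dynamics import ExternalWrench, inverse_dynamics_raw, root_coordinates
from .gcp import wrench_from_kinematics
from .model import Model, segment_kinematics
from .muscle import (active_force_length, force_velocity,
                     passive_force_length, rigid_tendon_state)
from .tables import TimeSeriesTable

__all__ = ["OcpFormulation", "FormulationError", "TrackingOptimization",
           "VerificationOptimization", "DesignOptimization",
           "kinetic_consistency_residual", "periodicity_residuals",
           "builtin_terms", "standardized_cost", "continuous_term",
           "bounds_from_range", "solution_tables"]

KINETIC_BOUND = 0.01          # N*m
RESIDUAL_FORCE_BOUND = 1.0    # N
RESIDUAL_MOMENT_BOUND = 0.1   # N*m
PERIODICITY_BOUND = 0.05      # rad


class FormulationError(ValueError):
    pass


@dataclass
class SynergyController:
    """One synergy-controlled muscle group: fixed synergy vectors W
    (n_synergies x n_muscles) whose time-varying commands are controls."""
    group: str
    muscles: list[str]
    W: np.ndarray


@dataclass
class OcpFormulation:
    """Declarative problem description shared by TO/VO/DO."""
    model: Model
    controllers: dict[str, str]              # coord -> torque|synergy|none
    muscle_params: dict = field(default_factory=dict)
    synergies: list[SynergyController] = field(default_factory=list)
    contact: dict = field(default_factory=dict)  # side -> ContactModel
    mesh_intervals: int = 25
    final_time: float | tuple = 1.0
    tracked: dict = field(default_factory=dict)  # name -> (n_nodes, k)
    terms: list[dict] = field(default_factory=list)
    kinetic_bound: float = KINETIC_BOUND
    residual_force_bound: float = RESIDUAL_FORCE_BOUND
    residual_moment_bound: float = RESIDUAL_MOMENT_BOUND
    periodic: bool = False
    periodicity_bound: float = PERIODICITY_BOUND
    periodicity_exclude: tuple = ()
    range_scale_factor: float = 0.8
    static_parameters: list[tuple] = field(default_factory=list)
    model_modification: callable | None = None   # p -> dict of overrides
    user_terms: list = field(default_factory=list)
    synergy_command_bound: float = 3.0
    gravity: tuple = (0.0, -9.81)

    def validate(self, require_consistency: bool = True):
        n_mus = {m.name for m in []}
        coords = self.model.coordinate_names
        for c, mode in self.controllers.items():
            if c not in coords:
                raise FormulationError(f"unknown coordinate {c!r}")
            if mode not in ("torque", "synergy", "both", "none"):
                raise FormulationError(f"bad controller type {mode!r}")
            if mode in ("synergy", "both"):
                spanned = any(
                    c in self.model.muscles[m].moment_arms
                    for sc in self.synergies for m in sc.muscles)
                if not spanned:
                    raise FormulationError(
                        f"synergy-controlled coordinate {c!r} is spanned "
                        "by no muscle")
        for c in coords:
            if c not in self.controllers:
                raise FormulationError(f"coordinate {c!r} has no "
                                       "controller entry (use 'none')")


def kinetic_consistency_residual(form: OcpFormulation, Q, V, A,
                                 torques: dict, activations: dict):
    """Per-controlled-coordinate residual ID_j - (torque_j + muscle
    moments_j), vectorized over frames."""
    model = form.model
    ext = _contact_wrenches(form, Q, V)
    tau = inverse_dynamics_raw(model, Q, V, A, external=ext,
                               gravity=np.asarray(form.gravity))
    mus_mom = _muscle_moments(form, Q, V, activations)
    out = {}
    for c, mode in form.controllers.items():
        if mode == "none":
            continue
        j = model.coordinate_index(c)
        r = tau[j].copy()
        if mode in ("torque", "both") and c in torques:
            r = r - torques[c]
        if mode in ("synergy", "both"):
            r = r - mus_mom.get(c, 0.0)
        out[c] = r
    return out


def periodicity_residuals(states: dict[str, np.ndarray],
                          exclude: tuple = ()) -> dict[str, float]:
    """Final-minus-initial differences for the selected trajectories."""
    return {name: float(traj[-1] - traj[0])
            for name, traj in states.items() if name not in exclude}


def _contact_wrenches(form: OcpFormulation, Q, V):
    if not form.contact:
        return []
    kin = segment_kinematics(form.model, Q, V)
    out = []
    for side, cm in form.contact.items():
        seg = form.model.contact[side]["hindfoot"]
        force, mz, _ = wrench_from_kinematics(cm, kin)
        out.append(ExternalWrench(seg, force, mz,
                                  np.zeros_like(force)))
    return out


def _muscle_moments(form: OcpFormulation, Q, V, activations):
    """Net muscle moments per coordinate from per-muscle activations."""
    model = form.model
    out: dict[str, np.ndarray] = {}
    for sc in form.synergies:
        for m in sc.muscles:
            a = activations[m]
            p = form.muscle_params[m]
            lmt = model.muscle_length(m, Q)
            vmt = model.muscle_velocity(m, Q, V)
            ln, vn, cp, _ = rigid_tendon_state(lmt, vmt, p)
            F = p.max_isometric_force * cp * (
                a * active_force_length(ln) * force_velocity(vn)
                + passive_force_length(ln))
            for c in model.muscles[m].moment_arms:
                r = model.muscle_moment_arm(m, c, Q)
                out[c] = out.get(c, 0.0) + r * F
    return out


def builtin_terms(form: OcpFormulation, time, Q, V, A, torques,
                  activations, alpha_act: float = 40.0,
                  alpha_work: float = 1.0, basal_w_per_kg: float = 1.2):
    """Built-in design-goal quantities computed from a trajectory.

    Returns braking/propulsive impulse (N*s, anteroposterior GRF), metabolic
    cost per unit time (W) and per distance (J/m), the whole-body angular
    momentum trajectory about the COM (kg m^2/s), and per-coordinate
    positive/negative joint mechanical energy (J).
    """
    model = form.model
    out = {}
    ext = _contact_wrenches(form, Q, V)
    if ext:
        fx = sum(np.asarray(w.force[0], float) for w in ext)
        out["braking_impulse"] = float(np.trapezoid(np.minimum(fx, 0), time))
        out["propulsive_impulse"] = float(
            np.trapezoid(np.maximum(fx, 0), time))
    power = metabolic_power(form, Q, V, activations, alpha_act, alpha_work,
                            basal_w_per_kg)
    T = time[-1] - time[0]
    out["metabolic_rate"] = float(np.trapezoid(power, time) / T)
    # distance walked by the root forward translation
    roots = root_coordinates(model)
    if roots:
        jx = model.coordinate_index(roots[0])
        dist = abs(Q[jx, -1] - Q[jx, 0])
        out["metabolic_per_distance"] = (
            float(np.trapezoid(power, time) / dist) if dist > 1e-9
            else np.inf)
    # whole-body angular momentum about the COM
    kin = segment_kinematics(model, Q, V)
    masses = {s.name: s.mass for s in model.segments.values()}
    total_m = sum(masses.values())
    com = np.zeros((2, Q.shape[1]))
    com_v = np.zeros_like(com)
    body = {}
    for name, seg in model.segments.items():
        p, pd, _ = kin[name].point(seg.com[:2])
        body[name] = (p, pd)
        com += masses[name] * p / total_m
        com_v += masses[name] * pd / total_m
    L = np.zeros(Q.shape[1])
    for name, seg in model.segments.items():
        p, pd = body[name]
        rel = p - com
        relv = pd - com_v
        L += masses[name] * (rel[0] * relv[1] - rel[1] * relv[0])
        L += seg.inertia * kin[name].phid
    out["angular_momentum"] = L
    # joint mechanical energy generation/absorption
    gen, absorb = {}, {}
    for c, tq in torques.items():
        j = model.coordinate_index(c)
        pw = tq * V[j]
        gen[c] = float(np.trapezoid(np.maximum(pw, 0), time))
        absorb[c] = float(np.trapezoid(np.maximum(-pw, 0), time))
    out["joint_energy_generation"] = gen
    out["joint_energy_absorption"] = absorb
    return out


def metabolic_power(form: OcpFormulation, Q, V, activations,
                    alpha_act: float = 40.0, alpha_work: float = 1.0,
                    basal_w_per_kg: float = 1.2):
    """Two-coefficient activation/work metabolic model: per-muscle power
    alpha_act * F_max * l_opt * a + alpha_work * max(0, -v_fiber * F_fiber),
    plus a basal rate proportional to body mass."""
    model = form.model
    total_m = sum(s.mass for s in model.segments.values())
    P = np.full(Q.shape[1:] if Q.ndim > 1 else (), basal_w_per_kg * total_m)
    for sc in form.synergies:
        for m in sc.muscles:
            p = form.muscle_params[m]
            a = activations[m]
            lmt = model.muscle_length(m, Q)
            vmt = model.muscle_velocity(m, Q, V)
            ln, vn, cp, _ = rigid_tendon_state(lmt, vmt, p)
            F = p.max_isometric_force * cp * (
                a * active_force_length(ln) * force_velocity(vn)
                + passive_force_length(ln))
            v_fiber = vmt * cp
            P = P + alpha_act * p.max_isometric_force \
                * p.optimal_fiber_length * np.clip(a, 0.0, None) \
                + alpha_work * np.clip(-v_fiber * F, 0.0, None)
    return P


# ---------------------------------------------------------------------------
# Problem builder
# ---------------------------------------------------------------------------

class _OcpBuilder:
    """Maps an OcpFormulation onto a Transcription."""

    def __init__(self, form: OcpFormulation):
        form.validate()
        self.form = form
        model = form.model
        self.coords = model.coordinate_names
        self.n = len(self.coords)
        self.torque_coords = [c for c in self.coords
                              if form.controllers.get(c) in
                              ("torque", "both")]
        self.n_syn = sum(sc.W.shape[0] for sc in form.synergies)
        self.nc = self.n + len(self.torque_coords) + self.n_syn
        self.ns = 2 * self.n
        Ax = np.zeros((self.ns, self.ns))
        Ax[:self.n, self.n:] = np.eye(self.n)
        Au = np.zeros((self.ns, self.nc))
        Au[self.n:, :self.n] = np.eye(self.n)
        self.Ax, self.Au = Ax, Au

    # -- control/state slicing ----------------------------------------------
    def split_controls(self, U):
        A = U[:, :self.n]
        torques = {c: U[:, self.n + i]
                   for i, c in enumerate(self.torque_coords)}
        syn = {}
        off = self.n + len(self.torque_coords)
        for sc in self.form.synergies:
            K = sc.W.shape[0]
            syn[sc.group] = U[:, off:off + K]
            off += K
        return A, torques, syn

    def activations(self, syn_commands, p=None):
        """Per-muscle activations from synergy commands (with the
        model-modification hook applied to the synergy vectors)."""
        out = {}
        for sc in self.form.synergies:
            W = sc.W
            if self.form.model_modification is not None and p is not None:
                mods = self.form.model_modification(np.asarray(p, float))
                W = mods.get(("synergy_vectors", sc.group), W)
            C = syn_commands[sc.group]
            Arec = C @ W
            for j, m in enumerate(sc.muscles):
                out[m] = Arec[:, j]
        return out

    def trajectories(self, X, U, p=None):
        Q = X[:, :self.n].T
        V = X[:, self.n:].T
        Acc, torques, syn = self.split_controls(U)
        acts = self.activations(syn, p)
        return Q, V, Acc.T, {c: t for c, t in torques.items()}, acts

    # -- transcription ------------------------------------------------------
    def build(self) -> Transcription:
        form = self.form
        tr = Transcription(self.ns, self.nc, self.Ax, self.Au,
                           n_intervals=form.mesh_intervals,
                           final_time=form.final_time,
                           n_params=len(form.static_parameters))
        # dynamics-consistency path constraint
        ctrl_coords = [c for c in self.coords
                       if form.controllers.get(c) not in (None, "none")]
        resid_coords = [c for c in root_coordinates(form.model)
                        if form.controllers.get(c) == "none"]

        def consistency(X, U, p):
            Q, V, Acc, torques, acts = self.trajectories(X, U, p)
            ext = _contact_wrenches(form, Q, V)
            tau = inverse_dynamics_raw(form.model, Q, V, Acc, external=ext,
                                       gravity=np.asarray(form.gravity))
            mus = _muscle_moments(form, Q, V, acts) if acts else {}
            rows = []
            for c in ctrl_coords:
                j = form.model.coordinate_index(c)
                r = tau[j].copy()
                mode = form.controllers[c]
                if mode in ("torque", "both"):
                    r = r - torques[c]
                if mode in ("synergy", "both"):
                    r = r - mus.get(c, 0.0)
                rows.append(r)
            for c in resid_coords:
                rows.append(tau[form.model.coordinate_index(c)])
            return np.stack(rows, axis=1)

        lb, ub = [], []
        for c in ctrl_coords:
            lb.append(-form.kinetic_bound)
            ub.append(form.kinetic_bound)
        for c in resid_coords:
            b = (form.residual_force_bound
                 if form.model.coordinates[c].kind == "translational"
                 else form.residual_moment_bound)
            lb.append(-b)
            ub.append(b)
        if ctrl_coords or resid_coords:
            tr.path_constraints.append(PathConstraint(
                "kinetic_consistency", consistency,
                np.array(lb), np.array(ub)))

        if form.periodic:
            rows, plb, pub = [], [], []
            nn = tr.n_nodes
            for i, c in enumerate(self.coords):
                if c in form.periodicity_exclude:
                    continue
                for off in (i, self.n + i):       # position and velocity
                    row = np.zeros(tr.nvar)
                    row[(nn - 1) * self.ns + off] = 1.0
                    row[off] = -1.0
                    rows.append(row)
                    b = (form.periodicity_bound if off == i
                         else 10 * form.periodicity_bound)
                    plb.append(-b)
                    pub.append(b)
            tr.linear_constraints.append(LinearEquality(
                "periodicity", np.array(rows), np.array(plb),
                np.array(pub)))
        return tr

    def add_bounds(self, tr: Transcription, X0, U0):
        rsf = self.form.range_scale_factor
        slo, shi = bounds_from_range(X0.min(axis=0), X0.max(axis=0), rsf)
        clo, chi = bounds_from_range(U0.min(axis=0), U0.max(axis=0), rsf)
        # synergy commands are non-negative
        off = self.n + len(self.torque_coords)
        clo[off:] = np.maximum(clo[off:], 0.0)
        chi[off:] = np.minimum(np.maximum(chi[off:], 0.5),
                               self.form.synergy_command_bound)
        tr.state_bounds = (slo, shi)
        tr.control_bounds = (clo, chi)
        if self.form.static_parameters:
            plo = np.array([b[1] for b in self.form.static_parameters])
            phi = np.array([b[2] for b in self.form.static_parameters])
            tr.param_bounds = (plo, phi)


def _tracking_fun(builder, kind, names=None):
    n = builder.n

    def coords_fun(X, U, p):
        return X[:, [builder.coords.index(c) for c in names]]

    def vel_fun(X, U, p):
        return X[:, [n + builder.coords.index(c) for c in names]]

    def torque_fun(X, U, p):
        _, torques, _ = builder.split_controls(U)
        return np.column_stack([torques[c] for c in names])

    def synergy_fun(X, U, p):
        _, _, syn = builder.split_controls(U)
        return np.column_stack([syn[g] for g in names])

    def load_fun(X, U, p):
        Q, V, Acc, torques, acts = builder.trajectories(X, U, p)
        ext = _contact_wrenches(builder.form, Q, V)
        tau = inverse_dynamics_raw(builder.form.model, Q, V, Acc,
                                   external=ext,
                                   gravity=np.asarray(builder.form.gravity))
        return tau[[builder.form.model.coordinate_index(c)
                    for c in names]].T

    def grf_fun(X, U, p):
        Q, V, *_ = builder.trajectories(X, U, p)
        ext = _contact_wrenches(builder.form, Q, V)
        cols = []
        for w in ext:
            cols.extend([w.force[0], w.force[1], w.moment_z])
        return np.column_stack(cols)

    def activation_fun(X, U, p):
        _, _, syn = builder.split_controls(U)
        acts = builder.activations(syn, p)
        return np.column_stack([acts[m] for m in names])

    return {"coordinates": coords_fun, "velocities": vel_fun,
            "torques": torque_fun, "synergy_commands": synergy_fun,
            "loads": load_fun, "ground_reactions": grf_fun,
            "activations": activation_fun}[kind]


def _add_terms(builder, tr, term_list):
    for t in term_list:
        kind = t["type"]
        if kind == "metabolic_target":
            term = IntegralValueCost(
                "metabolic_target",
                lambda X, U, p: _metabolic_integrand(builder, X, U, p),
                center=t["center"], allowable=t["allowable"],
                weight=t.get("weight", 1.0))
        elif kind == "user":
            term = t["term"]
        else:
            term = TrackingCost(
                t.get("name", kind),
                _tracking_fun(builder, kind, t.get("names")),
                center=t.get("center", 0.0),
                allowable=t["allowable"], weight=t.get("weight", 1.0))
        tr.costs.append(term)


def _metabolic_integrand(builder, X, U, p):
    Q, V, _, _, acts = builder.trajectories(X, U, p)
    return metabolic_power(builder.form, Q, V, acts)


# ---------------------------------------------------------------------------
# The three tools
# ---------------------------------------------------------------------------

class _TreatmentToolBase:
    def __init__(self, form: OcpFormulation, maxiter: int = 300):
        self.form = form
        self.maxiter = maxiter
        self.builder = _OcpBuilder(form)

    def _check_tracked(self, needed: list[str]):
        for key in needed:
            if key not in self.form.tracked:
                raise FormulationError(
                    f"term requires tracked quantity {key!r} but it is "
                    "not in the tracked-quantities directory")

    def _solve(self, terms, X0, U0, p0=None, T0=None) -> OcpSolution:
        tr = self.builder.build()
        _add_terms(self.builder, tr, terms)
        self.builder.add_bounds(tr, X0, U0)
        sol = tr.solve(X0, U0, p0=p0, T0=T0, maxiter=self.maxiter)
        sol.term_values = dict(sol.term_values)
        return sol


class TrackingOptimization(_TreatmentToolBase):
    """TO: track every available experimental quantity under dynamics
    consistency constraints."""

    def solve(self, initial_states, initial_controls,
              allowables=None) -> OcpSolution:
        form = self.form
        allow = {"coordinates": 0.05, "velocities": 0.5, "loads": 2.0,
                 "ground_reactions": 10.0, "activations": 0.05,
                 **(allowables or {})}
        terms = []
        for kind in ("coordinates", "velocities", "loads",
                     "ground_reactions", "activations"):
            if kind not in form.tracked:
                continue
            names = form.tracked.get(kind + "_names")
            terms.append({"type": kind, "names": names,
                          "center": form.tracked[kind],
                          "allowable": allow[kind]})
        if not terms:
            raise FormulationError("TO has nothing to track")
        if any(form.controllers.get(c) in ("synergy", "both")
               for c in self.builder.coords) and not form.synergies:
            raise FormulationError(
                "synergy-driven TO requires synergy sets (NCP results) as "
                "part of the initial guess")
        return self._solve(terms, initial_states, initial_controls)


class VerificationOptimization(_TreatmentToolBase):
    """VO: track the TO-found synergy controls plus the positions of
    torque-controlled and uncontrolled coordinates — never the
    synergy-driven motion itself; constraints identical to TO."""

    def solve(self, to_solution: OcpSolution, allowables=None
              ) -> OcpSolution:
        form = self.form
        b = self.builder
        allow = {"synergy_commands": 0.02, "coordinates": 0.05,
                 **(allowables or {})}
        # formulation check: each coordinate exactly one of
        # tracked-by-controls (synergy) or tracked-by-position
        position_tracked = [c for c in b.coords
                            if form.controllers.get(c)
                            in ("none", "torque", "both")]
        for c in b.coords:
            mode = form.controllers.get(c)
            if mode is None:
                raise FormulationError(
                    f"coordinate {c!r} is neither controlled nor tracked")
        X0, U0 = to_solution.states, to_solution.controls
        _, torques0, syn0 = b.split_controls(U0)
        terms = []
        if form.synergies:
            groups = [sc.group for sc in form.synergies]
            terms.append({"type": "synergy_commands", "names": groups,
                          "center": np.column_stack(
                              [syn0[g] for g in groups]),
                          "allowable": allow["synergy_commands"]})
        if position_tracked:
            idx = [b.coords.index(c) for c in position_tracked]
            terms.append({"type": "coordinates", "names": position_tracked,
                          "center": X0[:, idx],
                          "allowable": allow["coordinates"]})
        if not terms:
            raise FormulationError("VO has nothing to track")
        return self._solve(terms, X0, U0)


class DesignOptimization(_TreatmentToolBase):
    """DO: VO-style control tracking plus treatment goal terms, static
    parameters (passed to the model-modification hook at every evaluation),
    user-defined cost terms, and optionally a free final time with
    time-stretched tracked controls."""

    def solve(self, vo_solution: OcpSolution, goal_terms=None,
              allowables=None) -> OcpSolution:
        form = self.form
        b = self.builder
        if isinstance(form.final_time, (tuple, list)) \
                and form.final_time[0] >= form.final_time[1]:
            raise FormulationError("free final time requires lo < hi bounds")
        allow = {"synergy_commands": 0.2, "coordinates": 0.1,
                 **(allowables or {})}
        X0, U0 = vo_solution.states, vo_solution.controls
        _, torques0, syn0 = b.split_controls(U0)
        terms = []
        if form.synergies:
            groups = [sc.group for sc in form.synergies]
            terms.append({"type": "synergy_commands", "names": groups,
                          "center": np.column_stack(
                              [syn0[g] for g in groups]),
                          "allowable": allow["synergy_commands"]})
        position_tracked = [c for c in b.coords
                            if form.controllers.get(c)
                            in ("none", "torque", "both")]
        if position_tracked:
            idx = [b.coords.index(c) for c in position_tracked]
            terms.append({"type": "coordinates", "names": position_tracked,
                          "center": X0[:, idx],
                          "allowable": allow["coordinates"]})
        terms.extend(goal_terms or [])
        for ut in form.user_terms:
            terms.append({"type": "user", "term": ut})
        p0 = np.array([sp[3] if len(sp) > 3 else 0.5 * (sp[1] + sp[2])
                       for sp in form.static_parameters])
        T0 = (vo_solution.final_time
              if isinstance(form.final_time, (tuple, list)) else None)
        try:
            return self._solve(terms, X0, U0, p0=p0, T0=T0)
        except FormulationError:
            raise
        except Exception as exc:
            if form.model_modification is not None or form.user_terms:
                raise RuntimeError(
                    f"design hook raised during solve: {exc!r}") from exc
            raise


def solution_tables(form: OcpFormulation, sol: OcpSolution) -> dict:
    """Derive the output tables (coordinates, generalized loads, ground
    reactions) from the solution's states and controls — never copied from
    the inputs."""
    b = _OcpBuilder(form)
    Q, V, Acc, torques, acts = b.trajectories(sol.states, sol.controls,
                                              sol.parameters)
    t = sol.time
    coords = TimeSeriesTable(t, {c: Q[i] for i, c in enumerate(b.coords)})
    ext = _contact_wrenches(form, Q, V)
    tau = inverse_dynamics_raw(form.model, Q, V, Acc, external=ext,
                               gravity=np.asarray(form.gravity))
    loads = TimeSeriesTable(t, {c: tau[i]
                                for i, c in enumerate(b.coords)})
    out = {"coordinates": coords, "loads": loads}
    if ext:
        cols = {}
        for w, side in zip(ext, form.contact):
            cols[f"{side}_force_x"] = w.force[0]
            cols[f"{side}_force_y"] = w.force[1]
            cols[f"{side}_moment_z"] = w.moment_z
        out["ground_reactions"] = TimeSeriesTable(t, cols)
    if acts:
        out["activations"] = TimeSeriesTable(
            t, {m: a for m, a in acts.items()})
    if torques:
        out["torques"] = TimeSeriesTable(t, dict(torques))
    return out
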