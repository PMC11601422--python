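"""Synthetic demo model and self-consistent gait-style datasets.

Every personalization tool in this package is testable by parameter recovery:
this module builds a planar two-legged demo model (pelvis root + thigh,
shank, hindfoot, toes per leg; 6 muscles per leg; marker set; spring-grid
foot contact) with known ground-truth parameters, and generates trials in
which every modality is mutually consistent by construction:

* joint trajectories are smooth periodic Fourier series (a rhythmic
  double-support motion, so both feet stay in ground contact);
* ground reactions come from the truth contact model along the motion;
* the root (pelvis) trajectory is adjusted by a small optimization so the
  root residual loads of inverse dynamics are near zero;
* muscle activations are synergy reconstructions H.W of truth synergies, and
  EMG is obtained by inverting the activation-dynamics chain, so the
  EMG-driven pipeline reproduces the truth exactly at the truth parameters;
* markers come from forward kinematics (plus optional Gaussian noise).

The generator's defaults are the study conditions of the test suite; they
are deliberately desk-scale (101-point single cycle, reduced contact grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dynamics import inverse_dynamics_raw, grf_to_wrenches
from .gcp import ContactModel, extract_foot, contact_wrench
from .model import Model, marker_positions, segment_kinematics
from .muscle import (MuscleTendonParams, inverse_activation_dynamics,
                     inverse_activation_nonlinearity, rigid_tendon_state,
                     muscle_tendon_force)
from .tables import GroundReactionData, MarkerData, TimeSeriesTable

__all__ = ["FixtureConfig", "make_demo_model", "generate_trial",
           "perturb_truth", "truth_muscle_moments"]

SEGMENT_GEOMETRY = {
    # name: (mass kg, inertia kg m^2, com in segment frame)
    "pelvis": (11.0, 0.08, (0.0, 0.0, 0.0)),
    "thigh": (8.0, 0.107, (0.0, -0.20, 0.0)),
    "shank": (3.5, 0.047, (0.0, -0.20, 0.0)),
    "hindfoot": (1.0, 0.005, (0.05, -0.05, 0.0)),
    "toes": (0.2, 0.0005, (0.03, -0.01, 0.0)),
}

HEEL_X, SOLE_Y, TOE_JOINT_X, TOE_TIP_X = -0.05, -0.07, 0.13, 0.21

# per-leg muscles: name -> (moment-arm polynomials per joint, l_opt, l_ts,
# F_max, pennation). Moment arms r(q) = c0 + c1 q.
MUSCLE_TABLE = {
    "hip_flexor":    ({"hip": (0.045, -0.01)}, 0.11, 0.14, 1200.0, 0.10),
    "hip_extensor":  ({"hip": (-0.055, 0.008)}, 0.13, 0.15, 2000.0, 0.00),
    "vasti":         ({"knee": (-0.042, 0.006)}, 0.10, 0.18, 2500.0, 0.05),
    "hamstring":     ({"hip": (-0.050, 0.0), "knee": (0.030, -0.005)},
                      0.11, 0.30, 1800.0, 0.12),
    "gastroc":       ({"knee": (0.018, 0.0), "ankle": (-0.045, 0.004)},
                      0.06, 0.36, 1600.0, 0.15),
    "tibialis":      ({"ankle": (0.038, -0.004)}, 0.07, 0.22, 800.0, 0.09),
}

TRUTH_ACTIVATION = {
    # per-muscle: emg scale, delay s, tau_act, tau_deact, nonlinearity A
    "hip_flexor":   (0.85, 0.040, 0.014, 0.055, -1.5),
    "hip_extensor": (0.75, 0.050, 0.016, 0.060, -2.0),
    "vasti":        (0.90, 0.035, 0.013, 0.050, -1.0),
    "hamstring":    (0.80, 0.045, 0.015, 0.065, -2.5),
    "gastroc":      (0.70, 0.055, 0.017, 0.058, -1.8),
    "tibialis":     (0.95, 0.030, 0.012, 0.045, -0.8),
}


@dataclass
class FixtureConfig:
    seed: int = 0
    cycle_duration: float = 1.0          # s
    n_points: int = 101
    marker_noise: float = 0.0            # m
    emg_noise: float = 0.0
    grid_rows: int = 1                   # reduced desk-scale contact grid
    grid_cols: int = 7
    n_synergies: int = 3
    hidden_emg: tuple = ()
    root_harmonics: int = 8
    with_contact: bool = True
    legs: tuple = ("r", "l")


def _contact_grid(rows: int, cols: int, rng=None,
                  nonuniform: bool = True) -> ContactModel:
    """Spring grid spanning heel to toe tip; stations past the toe joint
    attach to the toes segment (local coords at the zero pose)."""
    xs = np.linspace(HEEL_X + 0.01, TOE_TIP_X - 0.01, cols)
    stations = []
    for r in range(rows):
        for x in xs:
            if x <= TOE_JOINT_X:
                stations.append(("hindfoot", np.array([x, SOLE_Y])))
            else:
                stations.append(("toes",
                                 np.array([x - TOE_JOINT_X, SOLE_Y + 0.0])))
    n = rows * cols
    if nonuniform and rng is not None:
        base = 6e3 * (1.0 + 0.8 * np.sin(np.linspace(0, np.pi, cols)))
        k = np.tile(base, rows) * rng.uniform(0.85, 1.15, n)
    else:
        k = np.full(n, 6e3)
    return ContactModel(rows=rows, cols=cols, stiffness=k,
                        stations=stations, damping=0.5,
                        viscous_friction=0.1, dynamic_friction=0.0,
                        resting_length=0.012, smoothing=3e-3)


def make_demo_model(config: FixtureConfig | None = None
                    ) -> tuple[Model, dict]:
    """Build the planar demo model and its ground-truth parameter set.

    Returns (model, truth) where truth holds per-muscle
    :class:`MuscleTendonParams`, per-group synergy matrices, and per-foot
    contact models.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    m = Model()
    truth: dict = {"muscles": {}, "synergies": {}, "contact": {}}
    m.add_segment("pelvis", *SEGMENT_GEOMETRY["pelvis"])
    m.add_joint("ground_pelvis", "planar_root_3dof", "ground", "pelvis",
                coordinate_names=["pelvis_tx", "pelvis_ty", "pelvis_rz"])
    for mk in range(3):
        m.add_marker(f"pelvis_m{mk}", "pelvis",
                     (0.05 * (mk - 1), 0.05 + 0.02 * mk, 0.0))
    for side in config.legs:
        for seg in ("thigh", "shank", "hindfoot", "toes"):
            mass, inertia, com = SEGMENT_GEOMETRY[seg]
            m.add_segment(f"{seg}_{side}", mass, inertia, com)
        m.add_joint(f"hip_{side}", "pin", "pelvis", f"thigh_{side}",
                    location_in_parent=(0.0, -0.07, 0),
                    coordinate_names=[f"hip_{side}"])
        m.add_joint(f"knee_{side}", "pin", f"thigh_{side}", f"shank_{side}",
                    location_in_parent=(0.0, -0.40, 0),
                    coordinate_names=[f"knee_{side}"])
        m.add_joint(f"ankle_{side}", "pin", f"shank_{side}",
                    f"hindfoot_{side}", location_in_parent=(0.0, -0.40, 0),
                    coordinate_names=[f"ankle_{side}"])
        m.add_joint(f"toe_{side}", "oblique_pin", f"hindfoot_{side}",
                    f"toes_{side}", location_in_parent=(TOE_JOINT_X, -0.05, 0),
                    axis=(0.15, 0.15, 0.977), coordinate_names=[f"toe_{side}"])
        marker_spots = {
            "thigh": [(0.02, -0.1), (-0.02, -0.25), (0.03, -0.35)],
            "shank": [(0.02, -0.08), (-0.02, -0.22), (0.02, -0.38)],
            "hindfoot": [(-0.05, -0.02), (0.05, 0.01), (0.10, -0.04)],
            "toes": [(0.01, 0.0), (0.04, -0.01), (0.07, 0.0)],
        }
        for seg, spots in marker_spots.items():
            for k, (x, y) in enumerate(spots):
                m.add_marker(f"{seg}_{side}_m{k}", f"{seg}_{side}",
                             (x, y, 0.0))
        m.add_marker(f"midfoot_sup_{side}", f"hindfoot_{side}",
                     (0.06, 0.02, 0.0))
        members = []
        for mname, (arms, l_opt, l_ts, f_max, penn) in MUSCLE_TABLE.items():
            full = f"{mname}_{side}"
            arms_side = {f"{c}_{side}": np.asarray(v) for c, v in arms.items()}
            ref = l_ts + 0.75 * l_opt
            mu = m.add_muscle(full, ref, arms_side)
            scale, delay, tact, tdeact, A = TRUTH_ACTIVATION[mname]
            params = MuscleTendonParams(
                optimal_fiber_length=l_opt, tendon_slack_length=l_ts,
                max_isometric_force=f_max, pennation_at_optimal=penn,
                emg_scale=scale, electromechanical_delay=delay,
                activation_time_constant=tact,
                deactivation_time_constant=tdeact,
                activation_nonlinearity=A)
            mu.params = params
            truth["muscles"][full] = params
            members.append(full)
        m.add_muscle_group(f"leg_{side}", members)
        m.add_muscle_group(f"fiber_group_{side}",
                           [f"vasti_{side}", f"hip_extensor_{side}"])
        W = _truth_synergy_vectors(config.n_synergies, len(members), rng)
        truth["synergies"][f"leg_{side}"] = W
        grid = _contact_grid(config.grid_rows, config.grid_cols, rng)
        grid.stations = [(f"{seg}_{side}", loc) for seg, loc in grid.stations]
        truth["contact"][side] = grid
        m.contact[side] = {"hindfoot": f"hindfoot_{side}",
                           "toes": f"toes_{side}", "model": grid}
    m.validate()
    return m, truth


def _truth_synergy_vectors(n_syn, n_mus, rng) -> np.ndarray:
    """Non-negative synergy vectors, each row max-normalized to 1, with
    distinct dominant muscles per synergy."""
    W = rng.uniform(0.05, 0.4, size=(n_syn, n_mus))
    for k in range(n_syn):
        W[k, (2 * k) % n_mus] = 1.0
        W[k, (2 * k + 1) % n_mus] = 0.7
    return W / W.max(axis=1, keepdims=True)


def truth_synergy_activations(time, n_syn, duration, rng=None) -> np.ndarray:
    """Smooth periodic non-negative synergy activations H (F, n_syn):
    raised-cosine bumps at staggered phases."""
    t = np.asarray(time, float)
    H = np.empty((len(t), n_syn))
    for k in range(n_syn):
        phase = 2 * np.pi * (t / duration - k / n_syn)
        H[:, k] = 0.25 + 0.22 * (1 + np.cos(phase)) / 2 \
            + 0.08 * (1 + np.cos(2 * phase + 0.7 * k)) / 2
    return H


class _Harmonics:
    """Finite cosine series q(t) = dc + sum_k A_k cos(k w t + phi_k) with
    exact derivatives."""

    def __init__(self, w, dc=0.0, terms=()):
        self.w, self.dc, self.terms = w, dc, list(terms)

    def __add__(self, other):
        if self.w != other.w:
            raise ValueError("mismatched base frequency")
        return _Harmonics(self.w, self.dc + other.dc,
                          self.terms + other.terms)

    def __neg__(self):
        return _Harmonics(self.w, -self.dc,
                          [(-a, k, p) for a, k, p in self.terms])

    def __sub__(self, other):
        return self + (-other)

    def eval(self, t, order=0):
        t = np.asarray(t, float)
        out = np.full_like(t, self.dc if order == 0 else 0.0)
        for a, k, p in self.terms:
            kw = k * self.w
            arg = kw * t + p + order * np.pi / 2
            out = out + a * kw ** order * np.cos(arg)
        return out


def _joint_trajectories(model: Model, time: np.ndarray, duration: float):
    """Rhythmic double-support joint trajectories (both feet planted):
    hip/knee flexion waves with >25 degree excursions, the ankle
    compensating so the foot stays nearly flat (pitch ~ +-2 deg) and the
    contact springs stay engaged. Returns exact (Q, V, A)."""
    w = 2 * np.pi / duration
    t = np.asarray(time, float)
    d = np.deg2rad
    pelvis_rz = _Harmonics(w, 0.0, [(d(2.0), 1, -np.pi / 2)])
    hip = _Harmonics(w, d(-20.0), [(d(18.0), 1, 0.0),
                                   (d(3.0), 2, -np.pi / 2)])
    knee = _Harmonics(w, d(28.0), [(-d(24.0), 1, 0.0), (d(4.0), 2, 0.5)])
    foot_pitch = _Harmonics(w, 0.0, [(d(2.0), 1, 0.5 - np.pi / 2)])
    ankle = foot_pitch - pelvis_rz - hip - knee
    toe = _Harmonics(w, d(1.0), [(-d(1.0), 1, 0.0)])
    series = {"pelvis_rz": pelvis_rz}
    for side in ("r", "l"):
        if f"hip_{side}" in model.coordinates:
            series.update({f"hip_{side}": hip, f"knee_{side}": knee,
                           f"ankle_{side}": ankle, f"toe_{side}": toe})
    Q = np.zeros((model.n_coordinates, len(t)))
    V = np.zeros_like(Q)
    A = np.zeros_like(Q)
    for name, h in series.items():
        i = model.coordinate_index(name)
        Q[i], V[i], A[i] = h.eval(t, 0), h.eval(t, 1), h.eval(t, 2)
    # root translation guess (feet planted); overwritten by the
    # consistency adjustment
    tx, ty = _root_pose_guess(model, Q, t)
    Q[model.coordinate_index("pelvis_tx")] = tx
    Q[model.coordinate_index("pelvis_ty")] = ty
    return Q, V, A

def _root_pose_guess(model, Q, t):
    """Per-frame root translation keeping the hindfoot mid-sole point
    fixed in space (slightly into the springs)."""
    tx = np.zeros(len(t))
    ty = np.zeros(len(t))
    ix = model.coordinate_index("pelvis_tx")
    iy = model.coordinate_index("pelvis_ty")
    for f in range(len(t)):
        Qf = Q[:, f:f + 1].copy()
        Qf[ix] = 0.0
        Qf[iy] = 0.0
        kin = segment_kinematics(model, Qf)
        p, _, _ = kin["hindfoot_r"].point(np.array([0.05, SOLE_Y]))
        tx[f] = -p[0, 0]
        ty[f] = -p[1, 0] + 0.012 - 0.006   # resting length minus deflection
    return tx, ty


def _fourier_basis(t, duration, n_harm):
    """Fourier basis and its first two derivatives."""
    w = 2 * np.pi / duration
    cols, dcols, ddcols = [np.ones_like(t)], [np.zeros_like(t)], \
        [np.zeros_like(t)]
    for k in range(1, n_harm + 1):
        kw = k * w
        cols += [np.cos(kw * t), np.sin(kw * t)]
        dcols += [-kw * np.sin(kw * t), kw * np.cos(kw * t)]
        ddcols += [-kw ** 2 * np.cos(kw * t), -kw ** 2 * np.sin(kw * t)]
    return (np.column_stack(cols), np.column_stack(dcols),
            np.column_stack(ddcols))


def _contact_grf(model: Model, truth, Q, V, time) -> GroundReactionData:
    """Ground reactions from the truth contact models, stations evaluated
    on the full model (moments about the hindfoot-origin ground projection)."""
    from .gcp import wrench_from_kinematics
    kin = segment_kinematics(model, Q, V)
    feet = {}
    n = len(time)
    for side, cfg in model.contact.items():
        point = np.vstack([kin[cfg["hindfoot"]].o[0], np.zeros(n)])
        force, mz, _ = wrench_from_kinematics(truth["contact"][side], kin,
                                              expression_point=point)
        feet[side] = {
            "force": np.column_stack([force[0], force[1], np.zeros(n)]),
            "moment": np.column_stack([np.zeros((n, 2)), mz]),
            "point": np.column_stack([point[0], point[1], np.zeros(n)]),
        }
    return GroundReactionData(np.asarray(time, float), feet)


def _root_residuals(model, truth, Q, V, A, time):
    grf = _contact_grf(model, truth, Q, V, time)
    wrenches = grf_to_wrenches(model, grf, {
        s: model.contact[s]["hindfoot"] for s in model.contact})
    root_idx = [model.coordinate_index(c)
                for c in ("pelvis_tx", "pelvis_ty", "pelvis_rz")]
    tau = inverse_dynamics_raw(model, Q, V, A, external=wrenches,
                               coord_indices=root_idx)
    return tau[root_idx], grf


def _adjust_root(model, truth, Q0, V0, A0, time, duration, n_harm,
                 moment_scale=10.0):
    """Least-squares adjustment of the root Fourier coefficients so the
    root residual loads vanish along the cycle.

    The residual at each frame depends only on that frame's root position,
    velocity and acceleration, so the Jacobian w.r.t. the Fourier
    coefficients factorizes into a frame-local sensitivity (9 finite
    differences) times the analytic basis derivatives.
    """
    B, Bd, Bdd = _fourier_basis(time, duration, n_harm)
    root_idx = [model.coordinate_index(c)
                for c in ("pelvis_tx", "pelvis_ty", "pelvis_rz")]
    x0 = np.concatenate([np.linalg.lstsq(B, Q0[i], rcond=None)[0]
                         for i in root_idx])
    nb = B.shape[1]
    nF = len(time)
    scale = np.array([1.0, 1.0, moment_scale])

    def build(x):
        Q, V, A = Q0.copy(), V0.copy(), A0.copy()
        for k, i in enumerate(root_idx):
            c = x[k * nb:(k + 1) * nb]
            Q[i], V[i], A[i] = B @ c, Bd @ c, Bdd @ c
        return Q, V, A

    def fun(x):
        Q, V, A = build(x)
        res, _ = _root_residuals(model, truth, Q, V, A, time)
        return (scale[:, None] * res).ravel()

    def jac(x):
        Q, V, A = build(x)
        eps_q, eps_v, eps_a = 1e-6, 1e-5, 1e-4
        D = np.zeros((3, nF, 3, 3))   # res component, frame, coord, q/v/a
        for ci, i in enumerate(root_idx):
            for wi, (arr, eps) in enumerate(((Q, eps_q), (V, eps_v),
                                             (A, eps_a))):
                for sgn in (1.0, -1.0):
                    arr[i] += sgn * eps
                    r, _ = _root_residuals(model, truth, Q, V, A, time)
                    D[:, :, ci, wi] += sgn * r / (2 * eps)
                    arr[i] -= sgn * eps
        J = np.zeros((3 * nF, 3 * nb))
        for ci in range(3):
            block = (D[:, :, ci, 0][:, :, None] * B[None]
                     + D[:, :, ci, 1][:, :, None] * Bd[None]
                     + D[:, :, ci, 2][:, :, None] * Bdd[None])
            J[:, ci * nb:(ci + 1) * nb] = (
                scale[:, None, None] * block).reshape(3 * nF, nb)
        return J

    sol = least_squares(fun, x0, jac=jac, method="lm", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14, max_nfev=120)
    return build(sol.x)


def truth_muscle_moments(model: Model, truth, Q, V, time, activations,
                         coordinates=None):
    """Net joint moments produced by the truth muscle model for given
    activations (dict muscle -> (F,))."""
    from .muscle import muscle_joint_moments
    forces = {}
    for name, act in activations.items():
        p = truth["muscles"][name]
        lmt = model.muscle_length(name, Q)
        vmt = model.muscle_velocity(name, Q, V)
        ln, vn, cp, _ = rigid_tendon_state(lmt, vmt, p)
        F, _ = muscle_tendon_force(np.asarray(act), ln, vn, cp, p)
        forces[name] = F
    return muscle_joint_moments(model, Q, forces, coordinates)


def generate_trial(model: Model, truth: dict, config: FixtureConfig) -> dict:
    """Generate one fully self-consistent synthetic trial.

    Returns a dict with keys: time, coordinates, velocities, accelerations
    (tables), markers (MarkerData), grf (GroundReactionData or None),
    loads (net muscle moments per leg coordinate), emg (padded envelope
    table), activations, synergy_H, lmt/vmt/moment_arms per muscle, and
    root_residual diagnostics.
    """
    rng = np.random.default_rng(config.seed + 1)
    T = config.cycle_duration
    time = np.linspace(0.0, T, config.n_points)
    Q, V, A = _joint_trajectories(model, time, T)
    out: dict = {"time": time}
    if config.with_contact:
        Q, V, A = _adjust_root(model, truth, Q, V, A, time, T,
                               config.root_harmonics)
        res, grf = _root_residuals(model, truth, Q, V, A, time)
        out["grf"] = grf
        out["root_residual_rms"] = {
            "force_N": float(np.sqrt(np.mean(res[:2] ** 2))),
            "moment_Nm": float(np.sqrt(np.mean(res[2] ** 2))),
        }
    else:
        out["grf"] = None
    names = model.coordinate_names
    out["coordinates"] = TimeSeriesTable.from_matrix(time, Q.T, names)
    out["velocities"] = TimeSeriesTable.from_matrix(time, V.T, names)
    out["accelerations"] = TimeSeriesTable.from_matrix(time, A.T, names)

    # markers
    pos = marker_positions(model, Q)
    noisy = {n: p + rng.normal(0, config.marker_noise, p.shape)
             * np.array([1.0, 1.0, 0.0]) for n, p in pos.items()}
    out["markers"] = MarkerData(time, noisy)

    # synergy-consistent activations and EMG
    acts, emgs, H_all = {}, {}, {}
    for gname, W in truth["synergies"].items():
        members = model.muscle_groups[gname]
        H = truth_synergy_activations(time, W.shape[0], T)
        H_all[gname] = H
        A_rec = np.clip(H @ W, 0.0, 1.0)
        for j, mname in enumerate(members):
            acts[mname] = A_rec[:, j]
    pad = 0.2
    dt = time[1] - time[0]
    n_pad = int(np.round(pad / dt))
    t_pad = np.concatenate([time[0] - dt * np.arange(n_pad, 0, -1), time])
    for mname, a in acts.items():
        p = truth["muscles"][mname]
        a_neural = inverse_activation_nonlinearity(
            a, p.activation_nonlinearity)
        # periodic extension onto the padded grid, then invert dynamics
        a_ext = np.interp(np.mod(t_pad - time[0], T), time, a_neural,
                          period=None)
        e = inverse_activation_dynamics(t_pad, a_ext, p)
        env = np.clip(e / p.emg_scale, 0.0, 1.0)
        # shift forward by the delay: env_recorded(t) = env(t + delay)
        env_rec = np.interp(t_pad + p.electromechanical_delay, t_pad, env,
                            left=env[0], right=env[-1])
        if config.emg_noise > 0:
            env_rec = np.clip(env_rec + rng.normal(0, config.emg_noise,
                                                   env_rec.shape), 0, 1)
        emgs[mname] = env_rec
    out["activations"] = TimeSeriesTable(time, acts)
    out["synergy_H"] = H_all
    shown = {k: v for k, v in emgs.items() if k not in config.hidden_emg}
    out["emg"] = TimeSeriesTable(t_pad, shown, {"pad_points": n_pad})
    out["emg_all"] = TimeSeriesTable(t_pad, emgs, {"pad_points": n_pad})

    # muscle geometry tables and net muscle moments
    lmt = {m_: model.muscle_length(m_, Q) for m_ in model.muscles}
    vmt = {m_: model.muscle_velocity(m_, Q, V) for m_ in model.muscles}
    out["lmt"] = TimeSeriesTable(time, lmt)
    out["vmt"] = TimeSeriesTable(time, vmt)
    moments = truth_muscle_moments(model, truth, Q, V, time, acts)
    out["loads"] = TimeSeriesTable(
        time, {c: moments[c] for c in names
               if any(c in model.muscles[m_].moment_arms
                      for m_ in model.muscles)})
    return out


def generate_stance_trial(model: Model, truth: dict, side: str = "r",
                          duration: float = 0.7, n_points: int = 71) -> dict:
    """Synthetic single-foot stance for contact calibration: the extracted
    foot rolls from heel-weighted loading to forefoot push-off while the
    truth contact model generates the ground reactions.

    Returns time, the extracted FootModel, experimental foot coordinates
    (4, F), velocities, ground reaction force (2, F) / moment (F,) about
    the per-frame midfoot ground projection, and that projection (F,).
    """
    foot, _ = extract_foot(model, f"hindfoot_{side}", f"toes_{side}")
    contact = truth["contact"][side]
    t = np.linspace(0.0, duration, n_points)
    s = t / duration
    # foot pitch: heel strike (+6 deg) -> flat -> toe-off (-5 deg)
    rz = np.deg2rad(6.0) * np.cos(np.pi * s) ** 2 \
        - np.deg2rad(5.0) * np.sin(np.pi * s / 1.4) ** 2
    toe = np.deg2rad(6.0) * np.clip(s - 0.6, 0, None) ** 2 / 0.16
    # vertical: sink into the springs with a mid-stance peak load
    ty = -SOLE_Y + contact.resting_length \
        - 0.010 * np.sin(np.pi * s) ** 0.75 - 0.002
    tx = 0.003 * np.sin(2 * np.pi * s)
    Q = np.vstack([tx, ty, rz, toe])
    from scipy.interpolate import CubicSpline
    V = CubicSpline(t, Q.T)(t, 1).T
    kin = segment_kinematics(foot.model, Q, V)
    midfoot_x = kin[f"hindfoot_{side}"].point(np.array([0.06, 0.02]))[0][0]
    point = np.vstack([midfoot_x, np.zeros(n_points)])
    force, mz, _ = contact_wrench(foot, contact, Q, V,
                                  expression_point=point)
    return {"time": t, "foot": foot, "coordinates": Q, "velocities": V,
            "force": force, "moment": mz, "point": point,
            "midfoot_x": midfoot_x, "contact": contact}


def make_pendulum_ocp_fixture(n_intervals: int = 20, duration: float = 1.0,
                              coactivation: float = 0.25) -> dict:
    """Small synergy-driven fixture for the optimal-control tools: a
    single-joint limb actuated by an antagonist muscle pair under two
    synergies, moving through a periodic reference motion, with consistent
    states/controls for use as tracked quantities and initial guess.

    The co-contracting antagonists give the joint substantial intrinsic
    stiffness, so the motion is well-determined by the synergy commands
    alone (what verification optimization relies on).
    """
    from .dynamics import inverse_dynamics_raw
    from .muscle import (active_force_length, force_velocity,
                         passive_force_length, rigid_tendon_state)

    m = Model()
    m.add_segment("limb", mass=4.0, inertia=4.0 / 12, com=(0, -0.5, 0))
    m.add_joint("joint", "pin", "ground", "limb",
                coordinate_names=["theta"])
    flex_params = MuscleTendonParams(
        optimal_fiber_length=0.10, tendon_slack_length=0.20,
        max_isometric_force=2500.0)
    ext_params = MuscleTendonParams(
        optimal_fiber_length=0.10, tendon_slack_length=0.20,
        max_isometric_force=2500.0)
    # constant moment arms; reference lengths put fibers near optimal
    m.add_muscle("flexor", 0.20 + 0.085, {"theta": np.array([0.05])},
                 flex_params)
    m.add_muscle("extensor", 0.20 + 0.085, {"theta": np.array([-0.05])},
                 ext_params)
    m.add_muscle_group("limb_muscles", ["flexor", "extensor"])
    m.validate()
    params = {"flexor": flex_params, "extensor": ext_params}

    nn = n_intervals + 1
    t = np.linspace(0.0, duration, nn)
    w = 2 * np.pi / duration
    q = 0.3 + 0.25 * np.sin(w * t)
    v = 0.25 * w * np.cos(w * t)
    a = -0.25 * w ** 2 * np.sin(w * t)
    tau = inverse_dynamics_raw(m, q[None], v[None], a[None])[0]

    # activations solving the moment equation with a co-activation floor
    acts = np.zeros((nn, 2))
    gains = {}
    for j, name in enumerate(("flexor", "extensor")):
        p = params[name]
        lmt = m.muscle_length(name, np.vstack([q]))
        vmt = m.muscle_velocity(name, np.vstack([q]), np.vstack([v]))
        ln, vn, cp, _ = rigid_tendon_state(lmt, vmt, p)
        alpha = p.max_isometric_force * cp * active_force_length(ln) \
            * force_velocity(vn)
        beta = p.max_isometric_force * cp * passive_force_length(ln)
        r = m.muscle_moment_arm(name, "theta", np.vstack([q]))
        gains[name] = (r * alpha, r * beta)
    g_f, b_f = gains["flexor"]
    g_e, b_e = gains["extensor"]
    need = tau - b_f - b_e
    a_f = np.full(nn, coactivation)
    a_e = np.full(nn, coactivation)
    extra = need - g_f * coactivation - g_e * coactivation
    a_f = np.where(extra >= 0, coactivation + extra / g_f, coactivation)
    a_e = np.where(extra < 0, coactivation + extra / g_e, coactivation)
    acts[:, 0], acts[:, 1] = a_f, a_e

    W = np.array([[1.0, 0.25], [0.25, 1.0]])
    C = acts @ np.linalg.inv(W)
    if C.min() < 0:
        raise RuntimeError("fixture synergy commands went negative")
    X0 = np.column_stack([q, v])
    U0 = np.column_stack([a, C])
    return {"model": m, "params": params, "time": t, "q": q, "v": v,
            "accel": a, "tau": tau, "activations": acts, "W": W,
            "commands": C, "states": X0, "controls": U0,
            "duration": duration, "n_intervals": n_intervals,
            "group": "limb_muscles", "muscles": ["flexor", "extensor"]}


_TRIAL_CACHE: dict = {}


def get_demo_trial(config: FixtureConfig | None = None):
    """Demo model + truth + one generated trial, cached per configuration
    (trial generation involves the root-consistency optimization, which is
    worth reusing across tests)."""
    config = config or FixtureConfig()
    key = (config.seed, config.cycle_duration, config.n_points,
           config.marker_noise, config.emg_noise, config.grid_rows,
           config.grid_cols, config.n_synergies, tuple(config.hidden_emg),
           config.root_harmonics, config.with_contact, tuple(config.legs))
    if key not in _TRIAL_CACHE:
        model, truth = make_demo_model(config)
        trial = generate_trial(model, truth, config)
        _TRIAL_CACHE[key] = (model, truth, trial)
    return _TRIAL_CACHE[key]


def perturb_truth(truth: dict, magnitude: float, seed: int = 0) -> dict:
    """Initial-guess parameter set: multiplicative lognormal perturbation of
    positive muscle parameters (magnitude = sigma of log), additive for
    delays. magnitude 0 returns an identical copy."""
    rng = np.random.default_rng(seed)
    out = {"muscles": {}, "synergies": {k: v.copy()
                                        for k, v in truth["synergies"].items()},
           "contact": {k: v.copy() for k, v in truth["contact"].items()}}
    for name, p in truth["muscles"].items():
        f = lambda: float(np.exp(rng.normal(0.0, magnitude)))
        out["muscles"][name] = p.replace(
            optimal_fiber_length=p.optimal_fiber_length * f(),
            tendon_slack_length=p.tendon_slack_length * f(),
            emg_scale=float(np.clip(p.emg_scale * f(), 0.05, 1.0)),
            electromechanical_delay=float(np.clip(
                p.electromechanical_delay + rng.normal(0, magnitude * 0.1),
                0.0, 0.2)),
            activation_time_constant=p.activation_time_constant * f(),
            deactivation_time_constant=p.deactivation_time_constant * f(),
        )
    return out
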