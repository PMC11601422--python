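"""Neural Control Personalization (NCP).

Represents each muscle group's control as muscle synergies: non-negative
time-varying synergy activations H (frames x synergies) and non-negative
time-invariant synergy vectors W (synergies x muscles), with muscle
activations reconstructed as H.W. The tool fits H and W so that

* joint moments produced by the muscle model under H.W match the
  inverse-dynamics moments,
* reconstructed activations match MTP activations when available
  (otherwise an activation-minimization term keeps the non-unique solution
  small and of expected magnitude),
* grouped activations (and normalized fiber lengths) stay consistent,

subject to non-negativity and, per synergy, a vector-sum equality
constraint sum_m W[k, m] = C * n_muscles (C = 1 here). On output each
synergy vector is normalized so its largest weight is one, with the
corresponding synergy activation rescaled inversely, leaving H.W unchanged.
Synergy vectors can be shared between (e.g. left/right) groups.

Because the rigid-tendon muscle force is linear in activation at fixed
kinematics, the cost is a least-squares form in the bilinear product H.W,
and analytic gradients are available throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import Model
from .muscle import (active_force_length, force_velocity,
                     passive_force_length, rigid_tendon_state)
from .tables import TimeSeriesTable

__all__ = ["SynergySet", "reconstruct_activations", "vaf",
           "synergy_sum_residual", "normalize_synergy_set",
           "NeuralControlPersonalizer", "NcpSettings"]


@dataclass
class SynergySet:
    group: str
    muscles: list[str]
    W: np.ndarray                 # (n_synergies, n_muscles), non-negative
    H: np.ndarray                 # (n_frames, n_synergies), non-negative
    normalized: bool = False

    def __post_init__(self):
        self.W = np.asarray(self.W, float)
        self.H = np.asarray(self.H, float)
        if self.W.ndim != 2 or self.H.ndim != 2 \
                or self.H.shape[1] != self.W.shape[0]:
            raise ValueError("inconsistent synergy matrix shapes")
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("synergy matrices must be non-negative")

    @property
    def n_synergies(self) -> int:
        return self.W.shape[0]


def reconstruct_activations(H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Muscle activations H.W (frames x muscles)."""
    H = np.asarray(H, float)
    W = np.asarray(W, float)
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: H {H.shape} vs W {W.shape}")
    return H @ W


def vaf(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Uncentered variability accounted for, percent:
    100 (1 - ||orig - recon||_F^2 / ||orig||_F^2)."""
    original = np.asarray(original, float)
    reconstructed = np.asarray(reconstructed, float)
    if original.shape != reconstructed.shape:
        raise ValueError("shape mismatch")
    denom = float(np.sum(original ** 2))
    if denom == 0.0:
        raise ValueError("VAF undefined for an all-zero signal")
    return 100.0 * (1.0 - float(np.sum((original - reconstructed) ** 2))
                    / denom)


def synergy_sum_residual(W: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Per-synergy residual sum_m W[k, m] - C * n_muscles."""
    W = np.atleast_2d(np.asarray(W, float))
    return W.sum(axis=1) - C * W.shape[1]


def normalize_synergy_set(s: SynergySet) -> SynergySet:
    """Scale each synergy vector so its largest weight is 1, rescaling the
    matching synergy activation column so H.W is unchanged."""
    peaks = s.W.max(axis=1)
    bad = np.where(peaks <= 0)[0]
    if bad.size:
        raise ValueError(f"synergy {bad[0]} of group {s.group!r} is "
                         "all-zero and cannot be normalized")
    return SynergySet(s.group, list(s.muscles), s.W / peaks[:, None],
                      s.H * peaks[None, :], normalized=True)


@dataclass
class NcpSettings:
    groups: dict[str, int]                  # group name -> n_synergies
    tracked_coordinates: list[str]
    moment_allowable: float = 2.0           # N*m
    activation_allowable: float = 0.05
    activation_min_allowable: float = 0.05  # no-MTP mode
    similarity_allowable: float = 0.2       # grouped activations
    shared_vectors: list[tuple[str, str]] = field(default_factory=list)
    sum_constant: float = 1.0
    max_iter: int = 500
    seed: int = 0


class NeuralControlPersonalizer:
    """Fits per-group synergy sets against ID moments and (optionally) MTP
    activations.

    Fitted attributes: ``synergies_`` (normalized SynergySet per group),
    ``activations_`` (reconstruction table), ``diagnostics_`` (moment and
    activation RMSE, VAF, constraint violation before normalization).
    """

    def __init__(self, settings: NcpSettings):
        self.settings = settings

    def fit(self, model: Model, time: np.ndarray,
            coordinates: TimeSeriesTable, loads: TimeSeriesTable,
            muscle_params: dict, mtp_activations: TimeSeriesTable | None
            ) -> "NeuralControlPersonalizer":
        s = self.settings
        time = np.asarray(time, float)
        F = len(time)
        T = time[-1] - time[0]
        Q = coordinates.as_matrix(model.coordinate_names).T
        from scipy.interpolate import CubicSpline
        V = CubicSpline(time, Q.T)(time, 1).T
        w_t = np.zeros(F)
        dt = np.diff(time)
        w_t[:-1] += dt / 2
        w_t[1:] += dt / 2
        sq = np.sqrt(w_t / T)

        # per-group precomputation: force = alpha * a + beta, moments
        groups = []
        w_blocks: dict[str, int] = {}
        shared_of = {}
        for a, b in s.shared_vectors:
            shared_of[b] = a
        for g, K in s.groups.items():
            members = model.muscle_groups[g]
            M = len(members)
            if K > M:
                raise ValueError(f"group {g!r}: more synergies ({K}) than "
                                 f"muscles ({M})")
            alpha = np.zeros((F, M))
            beta = np.zeros((F, M))
            for j, m in enumerate(members):
                p = muscle_params[m]
                lmt = model.muscle_length(m, Q)
                vmt = model.muscle_velocity(m, Q, V)
                ln, vn, cp, _ = rigid_tendon_state(lmt, vmt, p)
                alpha[:, j] = p.max_isometric_force * cp \
                    * active_force_length(ln) * force_velocity(vn)
                beta[:, j] = p.max_isometric_force * cp \
                    * passive_force_length(ln)
            coords = [c for c in s.tracked_coordinates
                      if any(c in model.muscles[m].moment_arms
                             for m in members)]
            R = np.stack([[model.muscle_moment_arm(m, c, Q)
                           for m in members] for c in coords]) \
                if coords else np.zeros((0, M, F))    # (C, M, F)
            amtp = None
            if mtp_activations is not None:
                amtp = np.column_stack([mtp_activations[m]
                                        for m in members])
            groups.append({"name": g, "members": members, "K": K, "M": M,
                           "alpha": alpha, "beta": beta, "coords": coords,
                           "R": np.moveaxis(R, -1, 0), "amtp": amtp})
        # variable layout: per group H (F*K), then one W block per
        # non-shared group
        layout = []
        off = 0
        for gr in groups:
            gr["h_off"] = off
            off += F * gr["K"]
        for gr in groups:
            owner = shared_of.get(gr["name"], gr["name"])
            if owner not in w_blocks:
                w_blocks[owner] = off
                off += gr["K"] * gr["M"]
            gr["w_off"] = w_blocks[owner]
        nvar = off

        e_mom = s.moment_allowable
        e_act = (s.activation_allowable if mtp_activations is not None
                 else s.activation_min_allowable)
        e_sim = s.similarity_allowable
        loads_arr = {c: loads[c] for c in s.tracked_coordinates}

        def unpack(z):
            out = []
            for gr in groups:
                H = z[gr["h_off"]:gr["h_off"] + F * gr["K"]].reshape(
                    F, gr["K"])
                W = z[gr["w_off"]:gr["w_off"] + gr["K"] * gr["M"]].reshape(
                    gr["K"], gr["M"])
                out.append((H, W))
            return out

        def cost_grad(z):
            J = 0.0
            g_z = np.zeros_like(z)
            for gr, (H, W) in zip(groups, unpack(z)):
                A = H @ W                                   # (F, M)
                G = np.zeros_like(A)                        # dJ/dA
                # moment tracking
                for ci, c in enumerate(gr["coords"]):
                    P = gr["R"][:, ci, :] * gr["alpha"]     # (F, M)
                    mom = (P * A).sum(axis=1) \
                        + (gr["R"][:, ci, :] * gr["beta"]).sum(axis=1)
                    r = sq * (mom - loads_arr[c]) / e_mom
                    J += float(r @ r)
                    G += (2.0 * sq * r / e_mom)[:, None] * P
                # activation matching / minimization
                target = gr["amtp"] if gr["amtp"] is not None else 0.0
                r = sq[:, None] * (A - target) / e_act / np.sqrt(gr["M"])
                J += float(np.sum(r ** 2))
                G += 2.0 * sq[:, None] * r / e_act / np.sqrt(gr["M"])
                # grouped-activation similarity
                dev = A - A.mean(axis=1, keepdims=True)
                r = sq[:, None] * dev / e_sim / np.sqrt(gr["M"])
                J += float(np.sum(r ** 2))
                gd = 2.0 * sq[:, None] * r / e_sim / np.sqrt(gr["M"])
                G += gd - gd.mean(axis=1, keepdims=True)
                g_z[gr["h_off"]:gr["h_off"] + F * gr["K"]] += \
                    (G @ W.T).ravel()
                g_z[gr["w_off"]:gr["w_off"] + gr["K"] * gr["M"]] += \
                    (H.T @ G).ravel()
            return J, g_z

        # initial guess: NMF of MTP activations (or a flat prior)
        rng = np.random.default_rng(s.seed)
        z0 = np.zeros(nvar)
        from sklearn.decomposition import NMF
        for gr in groups:
            if gr["amtp"] is not None:
                A0 = gr["amtp"]
            else:
                # no-MTP mode: ridge moment fit per frame as the prior
                A0 = np.empty((F, gr["M"]))
                lam = 1e-2
                for f in range(F):
                    P = np.stack([gr["R"][f, ci, :] * gr["alpha"][f]
                                  for ci in range(len(gr["coords"]))])
                    rhs = np.array([loads_arr[c][f]
                                    - (gr["R"][f, ci, :]
                                       * gr["beta"][f]).sum()
                                    for ci, c in enumerate(gr["coords"])])
                    M_ = P.T @ P + lam * np.eye(gr["M"])
                    A0[f] = np.clip(np.linalg.solve(M_, P.T @ rhs),
                                    1e-4, 1.0)
            nmf = NMF(n_components=gr["K"], init="nndsvda", max_iter=1000,
                      random_state=s.seed, tol=1e-8)
            H0 = nmf.fit_transform(np.clip(A0, 1e-9, None))
            W0 = nmf.components_
            # align to the sum constraint by row/column rescaling
            rows = W0.sum(axis=1)
            rows[rows <= 0] = 1.0
            sc = s.sum_constant * gr["M"] / rows
            W0 = W0 * sc[:, None]
            H0 = H0 / sc[None, :]
            z0[gr["h_off"]:gr["h_off"] + F * gr["K"]] = H0.ravel()
            z0[gr["w_off"]:gr["w_off"] + gr["K"] * gr["M"]] = W0.ravel()

        # per-synergy sum equality constraints on each distinct W block
        cons = []
        for owner, woff in w_blocks.items():
            gr = next(g for g in groups if g["name"] == owner)
            K, M = gr["K"], gr["M"]
            for k in range(K):
                idx = woff + k * M + np.arange(M)
                target = s.sum_constant * M

                def con(z, idx=idx, target=target):
                    return z[idx].sum() - target

                def con_jac(z, idx=idx):
                    j = np.zeros_like(z)
                    j[idx] = 1.0
                    return j

                cons.append({"type": "eq", "fun": con, "jac": con_jac})

        sol = minimize(cost_grad, z0, jac=True, method="SLSQP",
                       bounds=[(0.0, None)] * nvar, constraints=cons,
                       options={"maxiter": s.max_iter, "ftol": 1e-12})
        self.n_iterations_ = int(sol.nit)
        self.converged_ = bool(sol.success)

        self.synergies_ = {}
        self.raw_synergies_ = {}
        acts = {}
        diag = {"moment_rmse": {}, "activation_rmse": {},
                "constraint_violation": 0.0, "vaf": {}}
        for gr, (H, W) in zip(groups, unpack(sol.x)):
            sset = SynergySet(gr["name"], gr["members"], np.clip(W, 0, None),
                              np.clip(H, 0, None))
            self.raw_synergies_[gr["name"]] = sset
            diag["constraint_violation"] = max(
                diag["constraint_violation"],
                float(np.abs(synergy_sum_residual(
                    sset.W, s.sum_constant)).max()))
            self.synergies_[gr["name"]] = normalize_synergy_set(sset)
            A = reconstruct_activations(H, W)
            for j, m in enumerate(gr["members"]):
                acts[m] = A[:, j]
            if gr["amtp"] is not None:
                diag["activation_rmse"][gr["name"]] = float(
                    np.sqrt(np.mean((A - gr["amtp"]) ** 2)))
                diag["vaf"][gr["name"]] = vaf(gr["amtp"], A)
            for ci, c in enumerate(gr["coords"]):
                P = gr["R"][:, ci, :] * gr["alpha"]
                mom = (P * A).sum(axis=1) \
                    + (gr["R"][:, ci, :] * gr["beta"]).sum(axis=1)
                diag["moment_rmse"][c] = float(
                    np.sqrt(np.mean((mom - loads_arr[c]) ** 2)))
        self.activations_ = TimeSeriesTable(time, acts)
        self.diagnostics_ = diag
        return self
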