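"""Muscle-Tendon Personalization (MTP).

EMG-driven calibration of Hill-model length parameters and activation
dynamics against inverse-dynamics joint moments. The optimization is
unconstrained nonlinear least squares over per-muscle design variables
(electromechanical delay, activation time constants, activation
nonlinearity, EMG scale, and fractional deviations of optimal fiber length
and tendon slack length from their initialized values), with the
standardized cost terms:

* joint-moment tracking error per tracked coordinate;
* parameter deviations from initial values;
* passive muscle force above a small threshold;
* inconsistency of grouped normalized fiber lengths, grouped EMG scale
  factors and grouped electromechanical delays (deviation of each member
  from its group mean).

Maximum isometric force is set once by Muscle-Tendon Length Initialization
(specific tension times muscle volume over optimal fiber length, with volume
from a height-mass regression) and is held constant during a run.

Synergy Extrapolation (SynX) estimates the excitations of muscles without
EMG data as free combinations of the time-varying components (PCA or NMF) of
the measured channels; the combination weights join the design variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .costs import term_residuals
from .model import Model
from .muscle import (MuscleTendonParams, activation_dynamics,
                     activation_nonlinearity, delay_and_scale,
                     muscle_tendon_force, rigid_tendon_state)
from .tables import TimeSeriesTable

__all__ = ["MtpTrial", "MtpSettings", "MuscleTendonPersonalizer",
           "mtl_initialization", "synx_estimate", "fmax_from_regression",
           "merge_results", "SPECIFIC_TENSION"]

SPECIFIC_TENSION = 60e3      # Pa


class MtpConfigError(ValueError):
    pass


@dataclass
class MtpTrial:
    """One trial's data bundle: coordinates, tracked ID loads, EMG
    envelopes on a padded grid (metadata key ``pad_points``), and the cycle
    duration. Muscle-tendon lengths/velocities and moment arms come from
    the model's muscle geometry at the trial coordinates."""
    coordinates: TimeSeriesTable
    loads: TimeSeriesTable
    emg: TimeSeriesTable
    cycle_duration: float

    @property
    def pad_points(self) -> int:
        return int(self.emg.metadata.get("pad_points", 0))


@dataclass
class MtpSettings:
    muscles: list[str]
    tracked_coordinates: list[str]
    free: tuple = ("delay", "time_constants", "nonlinearity", "scale",
                   "lengths")
    moment_allowable: float = 2.0              # N*m
    deviation_allowable: dict = field(default_factory=lambda: {
        "delay": 0.05, "tau": 0.02, "nonlinearity": 2.0, "scale": 0.5,
        "length_fraction": 0.1})
    passive_allowable: float = 0.02            # fraction of F_max
    similarity_allowable: dict = field(default_factory=lambda: {
        "fiber_length": 0.1, "scale": 0.2, "delay": 0.03})
    similarity_groups: list[str] = field(default_factory=list)
    length_fraction_bound: float = 0.3
    synx_method: str = "nmf"                   # 'nmf' | 'pca'
    synx_components: int | None = None         # None -> 95% VAF rule
    synx_muscles: list[str] = field(default_factory=list)
    max_nfev: int = 400
    n_restarts: int = 1         # extra jittered starts; best cost wins
    restart_seed: int = 0
    restart_jitter: float = 0.3  # fraction of the half bound range


def fmax_from_regression(height_m: float, mass_kg: float,
                         volume_fraction: float, optimal_fiber_length: float,
                         specific_tension: float = SPECIFIC_TENSION) -> float:
    """Maximum isometric force sigma * V / l_opt with per-muscle volume a
    fraction of the regression lower-limb muscle volume
    V_total [cm^3] = 47 * mass * height + 1285."""
    v_total = (47.0 * mass_kg * height_m + 1285.0) * 1e-6   # m^3
    return specific_tension * v_total * volume_fraction / optimal_fiber_length


def mtl_initialization(model: Model, trials: list[MtpTrial],
                       muscles: list[str],
                       height_m: float = 1.75, mass_kg: float = 75.0,
                       volume_fractions: dict[str, float] | None = None,
                       set_fmax: bool = False
                       ) -> dict[str, MuscleTendonParams]:
    """Initial length parameters placing each muscle's normalized fiber
    length trajectory on the ascending limb.

    The observed muscle-tendon length range is mapped onto normalized fiber
    lengths [0.6, 0.9]; a constant trajectory is placed at the region
    midpoint 0.75. With ``set_fmax`` the maximum isometric force is
    recomputed from the volume regression (and then held constant by the
    optimizer); otherwise existing values are kept.
    """
    out = {}
    for name in muscles:
        lmts = []
        for tr in trials:
            Q = tr.coordinates.as_matrix(model.coordinate_names).T
            lmts.append(model.muscle_length(name, Q))
        lmt = np.concatenate(lmts)
        lo, hi = float(lmt.min()), float(lmt.max())
        prior = model.muscles[name].params or MuscleTendonParams()
        span = hi - lo
        if span < 1e-9:
            l_opt = prior.optimal_fiber_length
            l_ts = lo - 0.75 * l_opt
        else:
            l_opt = span / 0.3
            l_ts = lo - 0.6 * l_opt
        if l_ts <= 0:       # anatomically impossible placement; flag by
            l_ts = 1e-3     # best-fit centering at the shortest feasible
        f_max = prior.max_isometric_force
        if set_fmax:
            frac = (volume_fractions or {}).get(name, 0.05)
            f_max = fmax_from_regression(height_m, mass_kg, frac, l_opt)
        out[name] = prior.replace(optimal_fiber_length=l_opt,
                                  tendon_slack_length=l_ts,
                                  max_isometric_force=f_max)
    return out


def synx_estimate(envelopes: np.ndarray, method: str = "nmf",
                  n_components: int | None = None,
                  vaf_target: float = 95.0, random_state: int = 0):
    """Factorize measured envelope channels into time-varying components.

    envelopes: (F, n_measured). Returns dict with keys ``components``
    (F, k), ``weights`` (k, n_measured), ``vaf`` (percent), ``k``.
    The component count defaults to the smallest k reaching ``vaf_target``
    percent VAF on the measured channels.
    """
    E = np.asarray(envelopes, float)
    n_meas = E.shape[1]
    if n_components is not None and n_components > n_meas:
        raise ValueError("more components than measured channels")
    ks = ([n_components] if n_components is not None
          else list(range(1, n_meas + 1)))
    for k in ks:
        if method == "nmf":
            from sklearn.decomposition import NMF
            nmf = NMF(n_components=k, init="nndsvda", max_iter=2000,
                      random_state=random_state, tol=1e-10)
            H = nmf.fit_transform(np.clip(E, 0, None))
            W = nmf.components_
            recon = H @ W
        elif method == "pca":
            from sklearn.decomposition import PCA
            pca = PCA(n_components=k, random_state=random_state)
            scores = pca.fit_transform(E)
            H = np.column_stack([np.ones(len(E)), scores])
            W = np.vstack([pca.mean_, pca.components_])
            recon = np.clip(H @ W, 0.0, None)
        else:
            raise ValueError(f"unknown SynX method {method!r}")
        denom = float(np.sum(E ** 2))
        vaf = 100.0 * (1.0 - float(np.sum((E - recon) ** 2)) / denom)
        if vaf >= vaf_target or k == ks[-1]:
            return {"components": H, "weights": W, "vaf": vaf,
                    "k": H.shape[1], "method": method}


def merge_results(*param_sets: dict[str, MuscleTendonParams]
                  ) -> dict[str, MuscleTendonParams]:
    """Combine per-leg calibration results into one parameter dictionary
    (later sets may not redefine a muscle)."""
    out: dict[str, MuscleTendonParams] = {}
    for ps in param_sets:
        dup = set(out) & set(ps)
        if dup:
            raise ValueError(f"muscles calibrated twice: {sorted(dup)}")
        out.update(ps)
    return out


class MuscleTendonPersonalizer:
    """Calibrates muscle-tendon and activation-dynamics parameters.

    Fitted attributes: ``params_`` (per-muscle MuscleTendonParams),
    ``activations_`` (per-trial tables), ``diagnostics_`` (per-coordinate
    moment RMSE and term breakdown), ``synx_`` (factorization + weights).
    """

    _DV_SPECS = {
        # tag -> (free-class, bounds, deviation-allowable key)
        "delay": ("delay", (0.0, 0.2), "delay"),
        "tau_act": ("time_constants", (0.008, 0.05), "tau"),
        "tau_deact": ("time_constants", (0.02, 0.12), "tau"),
        "nonlin": ("nonlinearity", (-3.0, -1e-6), "nonlinearity"),
        "scale": ("scale", (0.05, 1.0), "scale"),
        "d_lopt": ("lengths", None, "length_fraction"),
        "d_lts": ("lengths", None, "length_fraction"),
    }

    def __init__(self, settings: MtpSettings):
        self.settings = settings

    # -- plumbing ------------------------------------------------------------
    def _validate(self, model: Model, trials: list[MtpTrial]):
        s = self.settings
        for c in s.tracked_coordinates:
            if not any(c in model.muscles[m].moment_arms for m in s.muscles):
                raise MtpConfigError(
                    f"tracked coordinate {c!r} is spanned by no muscle")
            for tr in trials:
                if c not in tr.loads.columns:
                    raise MtpConfigError(
                        f"no moment column for tracked coordinate {c!r}")
        for g in s.similarity_groups:
            if g not in model.muscle_groups:
                raise MtpConfigError(f"unknown muscle group {g!r}")
        for m in s.synx_muscles:
            if m not in s.muscles:
                raise MtpConfigError(f"SynX muscle {m!r} not in muscle set")
        for tr in trials:
            for m in s.muscles:
                if m not in s.synx_muscles and m not in tr.emg.columns:
                    raise MtpConfigError(f"no EMG channel for {m!r}")

    def _pack(self, init: dict[str, MuscleTendonParams]):
        s = self.settings
        b = s.length_fraction_bound
        entries, x0, lo, hi = [], [], [], []
        for m in s.muscles:
            p = init[m]
            vals = {"delay": p.electromechanical_delay,
                    "tau_act": p.activation_time_constant,
                    "tau_deact": p.deactivation_time_constant,
                    "nonlin": min(p.activation_nonlinearity, -1e-6),
                    "scale": p.emg_scale, "d_lopt": 0.0, "d_lts": 0.0}
            for tag, (cls, bounds, _) in self._DV_SPECS.items():
                if cls not in s.free:
                    continue
                entries.append((m, tag))
                x0.append(vals[tag])
                blo, bhi = bounds if bounds else (-b, b)
                lo.append(blo)
                hi.append(bhi)
        return entries, np.array(x0), np.array(lo), np.array(hi)

    def _unpack(self, x, entries, init):
        params = {m: init[m] for m in self.settings.muscles}
        for (m, tag), v in zip(entries, x):
            p = params[m]
            if tag == "delay":
                p = p.replace(electromechanical_delay=float(v))
            elif tag == "tau_act":
                p = p.replace(activation_time_constant=float(v))
            elif tag == "tau_deact":
                p = p.replace(deactivation_time_constant=float(v))
            elif tag == "nonlin":
                p = p.replace(activation_nonlinearity=float(v))
            elif tag == "scale":
                p = p.replace(emg_scale=float(v))
            elif tag == "d_lopt":
                p = p.replace(optimal_fiber_length=init[m]
                              .optimal_fiber_length * (1.0 + float(v)))
            elif tag == "d_lts":
                p = p.replace(tendon_slack_length=init[m]
                              .tendon_slack_length * (1.0 + float(v)))
            params[m] = p
        return params

    # -- forward pipeline ----------------------------------------------------
    def _muscle_states(self, model, trial, params, synx_exc):
        """Per-muscle activation/fiber state and force along one trial."""
        s = self.settings
        t_pad = trial.emg.time
        n_pad = trial.pad_points
        time = t_pad[n_pad:]
        Q = trial.coordinates.as_matrix(model.coordinate_names).T
        from scipy.interpolate import CubicSpline
        V = CubicSpline(time, Q.T)(time, 1).T
        states = {}
        for m in s.muscles:
            p = params[m]
            if m in s.synx_muscles:
                exc = np.clip(synx_exc[m], 0.0, 1.0)
                a = activation_dynamics(time, exc, p)
            else:
                env = trial.emg[m]
                pad_dur = t_pad[n_pad] - t_pad[0] if n_pad else 0.0
                exc_pad = delay_and_scale(t_pad, env,
                                          p.electromechanical_delay,
                                          p.emg_scale, pad_duration=pad_dur)
                a = activation_dynamics(t_pad, np.clip(exc_pad, 0.0, 1.0),
                                        p)[n_pad:]
            a_nl = activation_nonlinearity(a, p.activation_nonlinearity)
            lmt = model.muscle_length(m, Q)
            vmt = model.muscle_velocity(m, Q, V)
            ln, vn, cp, _ = rigid_tendon_state(lmt, vmt, p)
            F, F_pas = muscle_tendon_force(a_nl, ln, vn, cp, p)
            states[m] = {"activation": a_nl, "force": F, "passive": F_pas,
                         "lnorm": ln}
        return states, Q, time

    def _residuals(self, x, model, trials, entries, init, synx):
        s = self.settings
        params = self._unpack(x[:len(entries)], entries, init)
        res = []
        for ti, trial in enumerate(trials):
            synx_exc = {}
            if s.synx_muscles:
                H = synx[ti]["components"][trial.pad_points:]
                k = H.shape[1]
                w = x[len(entries):].reshape(len(s.synx_muscles), k)
                for j, m in enumerate(s.synx_muscles):
                    synx_exc[m] = H @ w[j]
            states, Q, time = self._muscle_states(model, trial, params,
                                                  synx_exc)
            T = trial.cycle_duration
            for c in s.tracked_coordinates:
                mom = np.zeros(len(time))
                for m in s.muscles:
                    mom += model.muscle_moment_arm(m, c, Q) \
                        * states[m]["force"]
                res.append(term_residuals(time, mom - trial.loads[c], 0.0,
                                          s.moment_allowable, T))
            for m in s.muscles:
                p = params[m]
                res.append(term_residuals(
                    time, states[m]["passive"] / p.max_isometric_force,
                    0.0, s.passive_allowable, T))
            # grouped-similarity terms
            for g in s.similarity_groups:
                members = [m for m in model.muscle_groups[g]
                           if m in s.muscles]
                if len(members) < 2:
                    continue
                ln = np.stack([states[m]["lnorm"] for m in members])
                dev = ln - ln.mean(axis=0, keepdims=True)
                for row in dev:
                    res.append(term_residuals(
                        time, row, 0.0,
                        s.similarity_allowable["fiber_length"], T)
                        / np.sqrt(len(members)))
                for attr, key in (("emg_scale", "scale"),
                                  ("electromechanical_delay", "delay")):
                    vals = np.array([getattr(params[m], attr)
                                     for m in members])
                    res.append((vals - vals.mean())
                               / (s.similarity_allowable[key]
                                  * np.sqrt(len(members))))
        # parameter deviations from initial values
        for (m, tag), v, v0 in zip(entries, x[:len(entries)],
                                   self._x_init):
            allow = s.deviation_allowable[self._DV_SPECS[tag][2]]
            res.append(np.atleast_1d((v - v0) / allow
                                     / np.sqrt(max(len(entries), 1))))
        return np.concatenate(res)

    # -- fit -----------------------------------------------------------------
    def fit(self, model: Model, trials: list[MtpTrial],
            initial: dict[str, MuscleTendonParams] | None = None
            ) -> "MuscleTendonPersonalizer":
        s = self.settings
        self._validate(model, trials)
        if initial is None:
            initial = mtl_initialization(model, trials, s.muscles)
        fmax0 = {m: initial[m].max_isometric_force for m in s.muscles}
        entries, x0, lo, hi = self._pack(initial)
        self._x_init = x0.copy()
        # SynX factorization per trial (measured channels only)
        synx = []
        n_synx = 0
        if s.synx_muscles:
            for trial in trials:
                measured = [m for m in s.muscles
                            if m not in s.synx_muscles
                            and m in trial.emg.columns]
                E = np.column_stack([trial.emg[m] for m in measured])
                synx.append(synx_estimate(E, s.synx_method,
                                          s.synx_components))
            k = synx[0]["k"]
            n_synx = len(s.synx_muscles) * k
            x0 = np.concatenate([x0, np.full(n_synx, 0.1)])
            lo = np.concatenate([lo, np.full(n_synx, -5.0)])
            hi = np.concatenate([hi, np.full(n_synx, 5.0)])
        self.synx_ = synx

        rng = np.random.default_rng(s.restart_seed)
        sol = None
        for start in range(max(1, s.n_restarts)):
            xs = x0.copy()
            if start > 0:   # jittered restart against local minima
                xs = np.clip(x0 + rng.normal(0.0, s.restart_jitter,
                                             x0.shape) * (hi - lo) / 2,
                             lo, hi)
            cand = least_squares(
                self._residuals, xs, bounds=(lo, hi), method="trf",
                x_scale="jac", max_nfev=s.max_nfev,
                args=(model, trials, entries, initial, synx))
            if sol is None or cand.cost < sol.cost:
                sol = cand
        self.converged_ = bool(sol.success)
        self.params_ = self._unpack(sol.x[:len(entries)], entries, initial)
        for m in s.muscles:     # F_max immutability contract
            assert self.params_[m].max_isometric_force == fmax0[m]
        self.synx_weights_ = (
            sol.x[len(entries):].reshape(len(s.synx_muscles), -1)
            if n_synx else None)

        # diagnostics and activation outputs at the solution
        self.activations_ = []
        self.diagnostics_ = {"moment_rmse": {}, "cost": float(
            np.sum(sol.fun ** 2))}
        for ti, trial in enumerate(trials):
            synx_exc = {}
            if s.synx_muscles:
                H = synx[ti]["components"][trial.pad_points:]
                for j, m in enumerate(s.synx_muscles):
                    synx_exc[m] = H @ self.synx_weights_[j]
            states, Q, time = self._muscle_states(model, trial,
                                                  self.params_, synx_exc)
            self.activations_.append(TimeSeriesTable(
                time, {m: states[m]["activation"] for m in s.muscles}))
            for c in s.tracked_coordinates:
                mom = np.zeros(len(time))
                for m in s.muscles:
                    mom += model.muscle_moment_arm(m, c, Q) \
                        * states[m]["force"]
                err = mom - trial.loads[c]
                self.diagnostics_["moment_rmse"].setdefault(c, []).append(
                    float(np.sqrt(np.mean(err ** 2))))
        return self
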