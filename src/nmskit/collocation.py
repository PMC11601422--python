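"""Hermite-Simpson direct collocation on a fixed mesh.

The optimal-control problems here use an implicit dynamics formulation: the
states are coordinate positions and velocities and the controls include the
coordinate accelerations, so the state derivative is a *linear* map of
states and controls (qdot = v, vdot = a). All model nonlinearity lives in
path constraints (kinetic consistency, residual loads) and cost terms. As a
consequence the Hermite-Simpson defect constraints are linear whenever the
final time is fixed, and the transcribed problem is solved with
scipy.optimize's interior-point solver (trust-constr).

Path constraints and cost-term quantities are required to be *node-local*
(their value at mesh node k depends only on that node's states, controls
and the static parameters). Their Jacobians are then assembled from one
finite-difference sweep over the per-node inputs, which keeps the number of
function evaluations per Jacobian at n_states + n_controls + n_params
regardless of mesh size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import (LinearConstraint, NonlinearConstraint, minimize)
from scipy.sparse import lil_matrix

__all__ = ["PathConstraint", "TrackingCost", "IntegralValueCost",
           "ParameterCost", "LinearEquality", "Transcription", "OcpSolution",
           "bounds_from_range"]


def bounds_from_range(lo, hi, range_scale_factor: float,
                      floor: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Search bounds from an initial-guess range: the range extended on
    each side by range_scale_factor times its width; a degenerate range is
    expanded by an absolute floor."""
    if range_scale_factor < 0:
        raise ValueError("range scale factor must be non-negative")
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    if np.any(hi < lo):
        raise ValueError("range max must be >= min")
    width = hi - lo
    width = np.where(width <= 1e-12, floor / max(range_scale_factor, 1e-12)
                     if range_scale_factor > 0 else 0.0, width)
    ext = range_scale_factor * width
    lo2, hi2 = lo - ext, hi + ext
    deg = (hi - lo) <= 1e-12
    lo2 = np.where(deg & (ext <= 0), lo - floor, lo2)
    hi2 = np.where(deg & (ext <= 0), hi + floor, hi2)
    return lo2, hi2


@dataclass
class PathConstraint:
    """Node-local constraint lb <= fun(x_k, u_k, p) <= ub at every node.

    fun(X, U, p) is vectorized: X (n_nodes, ns), U (n_nodes, nc) ->
    (n_nodes, m).
    """
    name: str
    fun: callable
    lb: np.ndarray
    ub: np.ndarray


@dataclass
class TrackingCost:
    """Continuous standardized tracking term: the quantity trajectory
    fun(X, U, p) -> (n_nodes, m) is compared against ``center`` (scalar or
    per-node reference) and integrated: (1/T) int ((v - c)/e)^2 dt."""
    name: str
    fun: callable
    center: np.ndarray | float
    allowable: float
    weight: float = 1.0


@dataclass
class IntegralValueCost:
    """Standardized term on a time-averaged scalar: value =
    (1/T) int integrand(X, U, p) dt, cost = ((value - center)/e)^2."""
    name: str
    integrand: callable
    center: float
    allowable: float
    weight: float = 1.0


@dataclass
class ParameterCost:
    """Standardized term on a function of the static parameters."""
    name: str
    fun: callable                  # p -> scalar
    center: float
    allowable: float
    weight: float = 1.0


@dataclass
class LinearEquality:
    """Linear constraint rows on the packed variable vector (used for
    periodicity and boundary conditions)."""
    name: str
    rows: np.ndarray               # (m, nvar) or sparse
    lb: np.ndarray
    ub: np.ndarray


@dataclass
class OcpSolution:
    time: np.ndarray
    states: np.ndarray             # (n_nodes, ns)
    controls: np.ndarray           # (n_nodes, nc)
    parameters: np.ndarray
    final_time: float
    objective: float
    term_values: dict
    constraint_report: dict
    n_iterations: int
    success: bool
    message: str = ""


class Transcription:
    """Hermite-Simpson transcription of one optimal-control phase.

    Parameters
    ----------
    n_states, n_controls : sizes of the state and control vectors.
    deriv_state, deriv_control : matrices A_x (ns, ns) and A_u (ns, nc)
        with xdot = A_x x + A_u u (the implicit-dynamics linear map).
    n_intervals : mesh size N (N+1 nodes).
    final_time : fixed duration, or (lo, hi) bounds for a free final time.
    n_params : number of static parameters.
    """

    def __init__(self, n_states, n_controls, deriv_state, deriv_control,
                 n_intervals=25, final_time=1.0, n_params=0):
        self.ns = n_states
        self.nc = n_controls
        self.Ax = np.asarray(deriv_state, float)
        self.Au = np.asarray(deriv_control, float)
        self.N = int(n_intervals)
        self.np_ = int(n_params)
        self.free_time = isinstance(final_time, (tuple, list))
        if self.free_time:
            self.t_lo, self.t_hi = final_time
            if not self.t_hi > self.t_lo > 0:
                raise ValueError("free final time requires 0 < lo < hi")
        else:
            self.T = float(final_time)
            if self.T <= 0:
                raise ValueError("final time must be positive")
        self.path_constraints: list[PathConstraint] = []
        self.costs: list = []
        self.linear_constraints: list[LinearEquality] = []
        self.state_bounds = None
        self.control_bounds = None
        self.param_bounds = None

    # -- variable packing ----------------------------------------------------
    @property
    def n_nodes(self):
        return self.N + 1

    @property
    def nvar(self):
        return (self.n_nodes * (self.ns + self.nc) + self.np_
                + (1 if self.free_time else 0))

    def pack(self, X, U, p=None, T=None):
        parts = [np.asarray(X, float).ravel(), np.asarray(U, float).ravel()]
        parts.append(np.zeros(self.np_) if p is None
                     else np.asarray(p, float))
        if self.free_time:
            parts.append(np.atleast_1d(self.T_guess if T is None else T))
        return np.concatenate(parts)

    def unpack(self, z):
        nn = self.n_nodes
        X = z[:nn * self.ns].reshape(nn, self.ns)
        U = z[nn * self.ns:nn * (self.ns + self.nc)].reshape(nn, self.nc)
        p = z[nn * (self.ns + self.nc):nn * (self.ns + self.nc) + self.np_]
        T = z[-1] if self.free_time else self.T
        return X, U, p, float(T)

    def node_times(self, T=None):
        T = (self.T if not self.free_time else
             (self.T_guess if T is None else T))
        return np.linspace(0.0, T, self.n_nodes)

    def quad_weights(self, T):
        """Composite Simpson node/midpoint quadrature weights: node weight
        h/6 per adjacent interval, midpoint weight 2h/3."""
        h = T / self.N
        w_node = np.full(self.n_nodes, h / 3)
        w_node[0] = w_node[-1] = h / 6
        w_mid = np.full(self.N, 2 * h / 3)
        return w_node, w_mid

    def _midpoints(self, X, U, T):
        """Hermite-interpolated midpoint states and averaged midpoint
        controls, plus the chain-rule maps d x_m/d (x_k, x_k1, u_k, u_k1)."""
        h = T / self.N
        F = X @ self.Ax.T + U @ self.Au.T
        Xm = 0.5 * (X[:-1] + X[1:]) + h / 8 * (F[:-1] - F[1:])
        Um = 0.5 * (U[:-1] + U[1:])
        I = np.eye(self.ns)
        Mk = I / 2 + h / 8 * self.Ax
        Mk1 = I / 2 - h / 8 * self.Ax
        Nk = h / 8 * self.Au
        Nk1 = -h / 8 * self.Au
        return Xm, Um, (Mk, Mk1, Nk, Nk1)

    # -- defects -------------------------------------------------------------
    def _defect_matrix(self, T):
        """Sparse linear map D with D z' = defects, where z' excludes
        params/time. Exact for the linear derivative map."""
        ns, nc, N = self.ns, self.nc, self.N
        nn = N + 1
        h = T / N
        rows = lil_matrix((N * ns, nn * (ns + nc)))
        Ax, Au = self.Ax, self.Au
        I = np.eye(ns)
        # x_m = (x_k + x_k1)/2 + h/8 (f_k - f_k1); u_m = (u_k + u_k1)/2
        # defect = x_k1 - x_k - h/6 (f_k + 4 f_m + f_k1)
        # expand f_m = Ax x_m + Au u_m
        cxk = -I - h / 6 * (Ax + 4 * (Ax @ (I / 2 + h / 8 * Ax)))
        cxk1 = I - h / 6 * (Ax + 4 * (Ax @ (I / 2 - h / 8 * Ax)))
        cuk = -h / 6 * (Au + 4 * (Ax @ (h / 8 * Au) + Au / 2))
        cuk1 = -h / 6 * (Au + 4 * (-Ax @ (h / 8 * Au) + Au / 2))
        for k in range(N):
            r = slice(k * ns, (k + 1) * ns)
            rows[r, k * ns:(k + 1) * ns] = cxk
            rows[r, (k + 1) * ns:(k + 2) * ns] = cxk1
            cu0 = nn * ns
            rows[r, cu0 + k * nc:cu0 + (k + 1) * nc] = cuk
            rows[r, cu0 + (k + 1) * nc:cu0 + (k + 2) * nc] = cuk1
        return rows.tocsr()

    # -- cost assembly -------------------------------------------------------
    def _term_value_grad(self, term, X, U, p, T):
        """(value, dJ/dX, dJ/dU, dJ/dp) for one cost term, evaluated with
        Simpson node+midpoint quadrature and node-local finite
        differences."""
        w_node, w_mid = self.quad_weights(T)
        w_node = w_node / T
        w_mid = w_mid / T
        Xm, Um, (Mk, Mk1, Nk, Nk1) = self._midpoints(X, U, T)
        eps = 1e-6

        def local_jacobian(fun, Xa, Ua):
            base = np.asarray(fun(Xa, Ua, p), float)
            if base.ndim == 1:
                base = base[:, None]
            dX = np.zeros((self.ns,) + base.shape)
            dU = np.zeros((self.nc,) + base.shape)
            dP = np.zeros((self.np_,) + base.shape)

            def ev(Xb, Ub, pb):
                out = np.asarray(fun(Xb, Ub, pb), float)
                return out[:, None] if out.ndim == 1 else out

            for i in range(self.ns):
                Xp = Xa.copy(); Xp[:, i] += eps
                Xq = Xa.copy(); Xq[:, i] -= eps
                dX[i] = (ev(Xp, Ua, p) - ev(Xq, Ua, p)) / (2 * eps)
            for i in range(self.nc):
                Up = Ua.copy(); Up[:, i] += eps
                Uq = Ua.copy(); Uq[:, i] -= eps
                dU[i] = (ev(Xa, Up, p) - ev(Xa, Uq, p)) / (2 * eps)
            for i in range(self.np_):
                pp = p.copy(); pp[i] += eps
                pm = p.copy(); pm[i] -= eps
                dP[i] = (ev(Xa, Ua, pp) - ev(Xa, Ua, pm)) / (2 * eps)
            return base, dX, dU, dP

        gX = np.zeros_like(X)
        gU = np.zeros_like(U)
        gp = np.zeros(self.np_)

        def chain_mid(cm_x, cm_u):
            """Accumulate midpoint gradient contributions onto the node
            gradient arrays. cm_x: (N, ns) dJ/dx_m; cm_u: (N, nc)."""
            # dJ/dx_k = Mk^T dJ/dx_m etc.; in row-vector form v^T M
            gX[:-1] += cm_x @ Mk
            gX[1:] += cm_x @ Mk1
            gU[:-1] += cm_x @ Nk + 0.5 * cm_u
            gU[1:] += cm_x @ Nk1 + 0.5 * cm_u

        if isinstance(term, TrackingCost):
            base, dX, dU, dP = local_jacobian(term.fun, X, U)
            basem, dXm, dUm, dPm = local_jacobian(term.fun, Xm, Um)
            center = np.asarray(term.center, float)
            if center.ndim >= 1 and center.shape[0] == self.n_nodes:
                c_node = center if center.ndim == 2 else center[:, None]
                c_mid = 0.5 * (c_node[:-1] + c_node[1:])
            else:
                c_node = c_mid = center
            dev = (base - c_node) / term.allowable
            devm = (basem - c_mid) / term.allowable
            J = term.weight * float(np.sum(w_node[:, None] * dev ** 2)
                                    + np.sum(w_mid[:, None] * devm ** 2))
            coef = term.weight * 2.0 * w_node[:, None] * dev \
                / term.allowable
            coefm = term.weight * 2.0 * w_mid[:, None] * devm \
                / term.allowable
            for i in range(self.ns):
                gX[:, i] += np.sum(coef * dX[i], axis=1)
            for i in range(self.nc):
                gU[:, i] += np.sum(coef * dU[i], axis=1)
            for i in range(self.np_):
                gp[i] += float(np.sum(coef * dP[i])
                               + np.sum(coefm * dPm[i]))
            cm_x = np.stack([np.sum(coefm * dXm[i], axis=1)
                             for i in range(self.ns)], axis=1) \
                if self.ns else np.zeros((self.N, 0))
            cm_u = np.stack([np.sum(coefm * dUm[i], axis=1)
                             for i in range(self.nc)], axis=1) \
                if self.nc else np.zeros((self.N, 0))
            chain_mid(cm_x, cm_u)
            return J, gX, gU, gp
        if isinstance(term, IntegralValueCost):
            base, dX, dU, dP = local_jacobian(term.integrand, X, U)
            basem, dXm, dUm, dPm = local_jacobian(term.integrand, Xm, Um)
            value = float(np.sum(w_node * base[:, 0])
                          + np.sum(w_mid * basem[:, 0]))
            dev = (value - term.center) / term.allowable
            J = term.weight * dev ** 2
            coef = term.weight * 2.0 * dev / term.allowable
            for i in range(self.ns):
                gX[:, i] += coef * w_node * dX[i][:, 0]
            for i in range(self.nc):
                gU[:, i] += coef * w_node * dU[i][:, 0]
            for i in range(self.np_):
                gp[i] += coef * (float(np.sum(w_node * dP[i][:, 0]))
                                 + float(np.sum(w_mid * dPm[i][:, 0])))
            cm_x = np.stack([coef * w_mid * dXm[i][:, 0]
                             for i in range(self.ns)], axis=1) \
                if self.ns else np.zeros((self.N, 0))
            cm_u = np.stack([coef * w_mid * dUm[i][:, 0]
                             for i in range(self.nc)], axis=1) \
                if self.nc else np.zeros((self.N, 0))
            chain_mid(cm_x, cm_u)
            term._last_value = value
            return J, gX, gU, gp
        if isinstance(term, ParameterCost):
            eps_p = 1e-6
            value = float(term.fun(p))
            dev = (value - term.center) / term.allowable
            J = term.weight * dev ** 2
            for i in range(self.np_):
                pp = p.copy(); pp[i] += eps_p
                pm = p.copy(); pm[i] -= eps_p
                gp[i] += (term.weight * 2.0 * dev / term.allowable
                          * (term.fun(pp) - term.fun(pm)) / (2 * eps_p))
            return J, gX, gU, gp
        raise TypeError(f"unknown cost term type {type(term)}")

    def objective(self, z, return_terms=False):
        X, U, p, T = self.unpack(z)
        total = 0.0
        terms = {}
        for term in self.costs:
            J, *_ = self._term_value_grad(term, X, U, p, T)
            terms[term.name] = J
            total += J
        if return_terms:
            return total, terms
        return total

    def _objective_grad(self, z):
        X, U, p, T = self.unpack(z)
        total = 0.0
        gX = np.zeros_like(X)
        gU = np.zeros_like(U)
        gp = np.zeros(self.np_)
        for term in self.costs:
            J, tX, tU, tp = self._term_value_grad(term, X, U, p, T)
            total += J
            gX += tX
            gU += tU
            gp += tp
        g = np.concatenate([gX.ravel(), gU.ravel(), gp])
        if self.free_time:
            # dT column by finite difference on the whole objective
            eps = 1e-6
            zp = z.copy(); zp[-1] += eps
            zm = z.copy(); zm[-1] -= eps
            g = np.concatenate([g, [(self.objective(zp)
                                     - self.objective(zm)) / (2 * eps)]])
        return total, g

    # -- path-constraint assembly -------------------------------------------
    def _path_fun(self, pc):
        def fun(z):
            X, U, p, T = self.unpack(z)
            return np.asarray(pc.fun(X, U, p), float).ravel()
        return fun

    def _path_jac(self, pc):
        nn = self.n_nodes
        eps = 1e-6

        def jac(z):
            X, U, p, T = self.unpack(z)
            base = np.asarray(pc.fun(X, U, p), float)
            m = base.shape[1]
            Jm = lil_matrix((nn * m, self.nvar))
            for i in range(self.ns):
                Xp = X.copy(); Xp[:, i] += eps
                Xm = X.copy(); Xm[:, i] -= eps
                d = (np.asarray(pc.fun(Xp, U, p))
                     - np.asarray(pc.fun(Xm, U, p))) / (2 * eps)
                for k in range(nn):
                    Jm[k * m:(k + 1) * m, k * self.ns + i] = d[k][:, None]
            cu0 = nn * self.ns
            for i in range(self.nc):
                Up = U.copy(); Up[:, i] += eps
                Um = U.copy(); Um[:, i] -= eps
                d = (np.asarray(pc.fun(X, Up, p))
                     - np.asarray(pc.fun(X, Um, p))) / (2 * eps)
                for k in range(nn):
                    Jm[k * m:(k + 1) * m, cu0 + k * self.nc + i] = \
                        d[k][:, None]
            cp0 = nn * (self.ns + self.nc)
            for i in range(self.np_):
                pp = p.copy(); pp[i] += eps
                pm = p.copy(); pm[i] -= eps
                d = (np.asarray(pc.fun(X, U, pp))
                     - np.asarray(pc.fun(X, U, pm))) / (2 * eps)
                Jm[:, cp0 + i] = d.ravel()[:, None]
            return Jm.tocsr()
        return jac

    # -- solve ---------------------------------------------------------------
    def solve(self, X0, U0, p0=None, T0=None, maxiter=400, tol=1e-8,
              verbose=0) -> OcpSolution:
        if self.free_time:
            self.T_guess = float(T0 if T0 is not None
                                 else 0.5 * (self.t_lo + self.t_hi))
        z0 = self.pack(X0, U0, p0, T0)
        nn = self.n_nodes
        constraints = []
        if self.free_time:
            def defects(z):
                X, U, p, T = self.unpack(z)
                D = self._defect_matrix(T)
                return D @ z[:nn * (self.ns + self.nc)]
            constraints.append(NonlinearConstraint(
                defects, 0.0, 0.0, jac="2-point"))
        else:
            D = self._defect_matrix(self.T)
            from scipy.sparse import hstack, csr_matrix
            Dfull = hstack([D, csr_matrix((D.shape[0],
                                           self.nvar - D.shape[1]))])
            constraints.append(LinearConstraint(Dfull, 0.0, 0.0))
        for pc in self.path_constraints:
            lb = np.tile(np.asarray(pc.lb, float), nn)
            ub = np.tile(np.asarray(pc.ub, float), nn)
            constraints.append(NonlinearConstraint(
                self._path_fun(pc), lb, ub, jac=self._path_jac(pc)))
        for lc in self.linear_constraints:
            constraints.append(LinearConstraint(lc.rows, lc.lb, lc.ub))

        lb = np.full(self.nvar, -np.inf)
        ub = np.full(self.nvar, np.inf)
        if self.state_bounds is not None:
            slo, shi = self.state_bounds
            lb[:nn * self.ns] = np.tile(slo, nn)
            ub[:nn * self.ns] = np.tile(shi, nn)
        if self.control_bounds is not None:
            clo, chi = self.control_bounds
            lb[nn * self.ns:nn * (self.ns + self.nc)] = np.tile(clo, nn)
            ub[nn * self.ns:nn * (self.ns + self.nc)] = np.tile(chi, nn)
        if self.np_ and self.param_bounds is not None:
            plo, phi = self.param_bounds
            cp0 = nn * (self.ns + self.nc)
            lb[cp0:cp0 + self.np_] = plo
            ub[cp0:cp0 + self.np_] = phi
        if self.free_time:
            lb[-1], ub[-1] = self.t_lo, self.t_hi
        if np.any(lb > ub):
            raise ValueError("infeasible variable bounds")
        z0 = np.clip(z0, lb, ub)

        from scipy.optimize import Bounds
        res = minimize(self._objective_grad, z0, jac=True,
                       method="trust-constr", constraints=constraints,
                       bounds=Bounds(lb, ub),
                       options={"maxiter": maxiter, "gtol": tol,
                                "xtol": 1e-12, "verbose": verbose,
                                "sparse_jacobian": True})
        X, U, p, T = self.unpack(res.x)
        total, terms = self.objective(res.x, return_terms=True)
        report = self._constraint_report(res.x)
        return OcpSolution(
            time=np.linspace(0, T, nn), states=X, controls=U, parameters=p,
            final_time=T, objective=total, term_values=terms,
            constraint_report=report, n_iterations=int(res.nit),
            success=bool(res.success) or res.status in (1, 2),
            message=str(res.message))

    def _constraint_report(self, z):
        nn = self.n_nodes
        X, U, p, T = self.unpack(z)
        D = self._defect_matrix(T)
        report = {"defect_max": float(np.max(np.abs(
            D @ z[:nn * (self.ns + self.nc)]), initial=0.0))}
        for pc in self.path_constraints:
            vals = np.asarray(pc.fun(X, U, p), float)
            viol = np.maximum(vals - pc.ub, 0) + np.maximum(pc.lb - vals, 0)
            report[pc.name] = float(viol.max(initial=0.0))
        for lc in self.linear_constraints:
            vals = np.asarray(lc.rows @ z, float)
            viol = np.maximum(vals - lc.ub, 0) + np.maximum(lc.lb - vals, 0)
            report[lc.name] = float(np.max(viol, initial=0.0))
        report["max_violation"] = max(v for v in report.values())
        return report
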