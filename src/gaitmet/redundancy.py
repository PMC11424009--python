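"""Muscle-redundancy optimal control over a gait cycle.

Given prescribed kinematics, inverse-dynamics moments, muscle-tendon lengths
and moment arms, solves for the muscle excitations/states that minimize the
sum of squared activations (plus heavily penalized reserve actuators) subject
to activation dynamics, fiber-tendon equilibrium, per-dof moment balance, and
cyclic state boundary conditions.  Four workflows are supported:

- GEN / PAS : minimal effort (the two differ only in which passive-curve
  parameters the caller supplies — generic or calibrated);
- TEN       : adds tendon stiffness factors of named tendon groups as design
  variables, shared across all supplied gait cycles;
- EMG       : additionally constrains tracked muscles' excitations to stay
  within a hard corridor (+/- tracking bound) around gain-scaled measured
  envelopes, the gains being free optimization variables.

Transcription: backward-Euler direct collocation on a uniform mesh with
states (activation, normalized fiber length) and controls (excitation,
normalized fiber velocity, reserve moments).  The NLP is solved with
scipy.optimize.minimize(method="trust-constr") using analytic sparse
constraint Jacobians.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import (
    Bounds,
    LinearConstraint,
    NonlinearConstraint,
    lsq_linear,
    minimize,
)

from .curves import (
    CurveConstants,
    GENERIC_CURVES,
    active_force_length,
    force_velocity,
    passive_force_length,
    tendon_force,
)
from .muscle import FIBER_DAMPING, activation_dynamics_rate, solve_fiber_equilibrium
from .trial import GaitTrial

__all__ = [
    "RedundancySolution",
    "SolverOptions",
    "static_optimize",
    "solve_redundancy",
    "personalize_tendon_stiffness",
    "moment_balance_residual",
]

WORKFLOWS = ("GEN", "PAS", "TEN", "EMG")


def static_optimize(gains, moments, w_reserve: float = 1e6, tau_scale=None,
                    bounds=(0.0, 1.0)):
    """Minimum-effort static muscle recruitment at one instant.

    Solves  min sum(a^2) + w_reserve * sum((res/tau_scale)^2)
    s.t.    gains @ a + res = moments,  bounds[0] <= a <= bounds[1]

    where ``gains[d, m]`` is muscle m's moment gain (N*m per unit activation)
    about dof d.  The reserve is eliminated exactly, leaving a bounded
    least-squares problem; with the default heavy reserve penalty the result
    matches the equality-constrained minimum-norm solution
    a_i = M * G_i / sum(G^2) (single dof, inactive bounds) to ~1e-7.

    Returns (activations, reserve moments).
    """
    G = np.atleast_2d(np.asarray(gains, dtype=float))
    tau = np.atleast_1d(np.asarray(moments, dtype=float))
    nd, nm = G.shape
    if tau_scale is None:
        tau_scale = np.maximum(np.abs(tau), 1.0)
    ts = np.broadcast_to(np.asarray(tau_scale, dtype=float), (nd,))
    A = np.vstack([np.sqrt(w_reserve) * G / ts[:, None], np.eye(nm)])
    rhs = np.concatenate([np.sqrt(w_reserve) * tau / ts, np.zeros(nm)])
    sol = lsq_linear(A, rhs, bounds=bounds, tol=1e-14)
    a = sol.x
    res = tau - G @ a
    return a, res


@dataclass
class SolverOptions:
    n_mesh: int = 50
    w_effort: float = 1.0
    w_effort_emg: float = 0.01
    w_reserve: float = 1000.0
    w_velocity: float = 1e-4
    emg_bound: float = 0.01
    gain_bounds: tuple = (0.05, 5.0)
    kt_bounds: tuple = (15.0, 45.0)
    tau_act: float = 0.015
    tau_deact: float = 0.060
    maxiter: int = 300
    gtol: float = 1e-7
    xtol: float = 1e-10
    constr_tol: float = 1e-7
    verbose: int = 0


@dataclass
class RedundancySolution:
    """States, controls and diagnostics of one solved gait cycle."""

    time: np.ndarray
    muscle_names: tuple
    dofs: tuple
    excitation: np.ndarray       # (nm, K)
    activation: np.ndarray       # (nm, K)
    lm_norm: np.ndarray          # (nm, K)
    vm_norm: np.ndarray          # (nm, K), units of vmax, + = lengthening
    fiber_force: np.ndarray      # (nm, K), N (active+passive+damping)
    ce_force: np.ndarray         # (nm, K), N (contractile element only)
    tendon_force: np.ndarray     # (nm, K), N
    reserve: np.ndarray          # (nd, K), N*m
    objective: dict
    status: dict
    kt: dict = field(default_factory=dict)
    emg_gains: dict = field(default_factory=dict)
    trial: GaitTrial = None

    @property
    def vmax(self):
        return self._vmax

    def reserve_share(self) -> dict:
        """Peak |reserve| over peak |moment| per dof; flags shares > 5%."""
        out = {}
        for j, dof in enumerate(self.dofs):
            peak = max(np.max(np.abs(self.trial.moments[j])), 1e-9)
            share = float(np.max(np.abs(self.reserve[j])) / peak)
            out[dof] = {"share": share, "flagged": share > 0.05}
        return out


class _TrialBlock:
    """Per-trial NLP data: mesh-resampled series and variable index maps."""

    def __init__(self, trial: GaitTrial, muscles, opts: SolverOptions, base: int,
                 cbase: int):
        self.trial_full = trial
        self.opts = opts
        n = opts.n_mesh
        tmesh = np.linspace(trial.time[0], trial.time[-1], n + 1)
        tr = trial.resample(tmesh)
        self.trial = tr
        self.t = tmesh
        self.h = np.diff(tmesh)
        self.K = n + 1
        self.nm = len(muscles)
        self.nd = len(tr.dofs)
        self.base = base
        self.cbase = cbase
        # trapezoid quadrature weights normalized by cycle duration
        w = np.zeros(self.K)
        w[:-1] += 0.5 * self.h
        w[1:] += 0.5 * self.h
        self.wq = w / tr.duration

        nm, nd, K = self.nm, self.nd, self.K
        self.S = 4 * nm + nd
        self.n_var = K * self.S
        k = np.arange(K)[:, None]
        m = np.arange(nm)[None, :]
        self.ia = base + k * self.S + m                      # (K, nm)
        self.ilm = self.ia + nm
        self.ivm = self.ia + 2 * nm
        self.ie = self.ia + 3 * nm
        self.ires = base + np.arange(K)[:, None] * self.S + 4 * nm + np.arange(nd)[None, :]
        # constraint row offsets
        self.r_eq = cbase
        self.r_act = self.r_eq + K * nm
        self.r_fib = self.r_act + (K - 1) * nm
        self.r_mom = self.r_fib + (K - 1) * nm
        self.r_per = self.r_mom + K * nd
        self.n_con = self.r_per + 2 * nm - cbase

        # per-muscle constant arrays
        self.fmax = np.array([p.fmax for p in muscles])
        self.lopt = np.array([p.l_opt for p in muscles])
        self.lslack = np.array([p.l_slack for p in muscles])
        self.sina = np.array([np.sin(p.alpha_opt) for p in muscles])
        self.vmax = np.array([p.vmax for p in muscles])
        self.kpe = np.array([p.k_pe for p in muscles])
        self.s0 = np.array([p.s0 for p in muscles])
        self.sm = np.array([p.s_m for p in muscles])
        self.kt_fixed = np.array([p.k_t for p in muscles])
        # data on the mesh
        self.lmt = tr.lmt                       # (nm, K)
        self.R = tr.arms                        # (nm, nd, K)
        self.tau = tr.moments                   # (nd, K)
        self.tau_scale = np.maximum(np.max(np.abs(self.tau), axis=1), 1.0)  # (nd,)
        # which (m, d) pairs have a nonzero arm anywhere
        self.span = [
            [m_ for m_ in range(nm) if np.any(np.abs(self.R[m_, d_]) > 1e-12)]
            for d_ in range(nd)
        ]


def _passive_raw(lm, kpe, s0, sm):
    den = np.expm1(kpe)
    ex = np.exp(kpe * (lm - s0) / sm)
    return (ex - 1.0) / den, ex * (kpe / sm) / den


class _Problem:
    """Assembles the multi-trial NLP (objective, constraints, Jacobians)."""

    def __init__(self, trials, muscles, workflow, opts: SolverOptions,
                 tendon_groups=None, emg_map=None,
                 constants: CurveConstants = GENERIC_CURVES):
        self.muscles = list(muscles)
        self.workflow = workflow
        self.opts = opts
        self.constants = constants
        self.nm = len(self.muscles)
        self.names = [p.name for p in self.muscles]
        # the EMG workflow weights effort weakly relative to data fidelity
        # (tracking corridor + moment balance identify the tendon parameters)
        self.w_eff = opts.w_effort_emg if workflow == "EMG" else opts.w_effort

        self.blocks = []
        base = 0
        cbase = 0
        for tr in trials:
            b = _TrialBlock(tr, self.muscles, opts, base, cbase)
            self.blocks.append(b)
            base += b.n_var
            cbase += b.n_con

        # tendon-stiffness design variables (one per group)
        self.groups = dict(tendon_groups or {})
        self.group_names = list(self.groups)
        self.kt0 = base
        base += len(self.group_names)
        self.muscle_group = np.full(self.nm, -1, dtype=int)
        for gi, gname in enumerate(self.group_names):
            for mname in self.groups[gname]:
                if mname in self.names:
                    self.muscle_group[self.names.index(mname)] = gi

        # EMG gain variables (one per tracked channel, shared across trials)
        self.emg_map = dict(emg_map or {})  # channel -> muscle name
        self.channels = list(self.emg_map)
        self.g0 = base
        base += len(self.channels)
        self.n_var = base
        self.n_con = cbase

    # ---------------- bounds and initial point ----------------
    def bounds(self):
        lo = np.empty(self.n_var)
        hi = np.empty(self.n_var)
        for b in self.blocks:
            lo[b.ia], hi[b.ia] = 0.0, 1.0
            lo[b.ilm], hi[b.ilm] = 0.3, 1.9
            lo[b.ivm], hi[b.ivm] = -1.0, 1.0
            lo[b.ie], hi[b.ie] = 0.0, 1.0
            lo[b.ires], hi[b.ires] = -10.0, 10.0
        kl, kh = self.opts.kt_bounds
        lo[self.kt0:self.kt0 + len(self.group_names)] = kl
        hi[self.kt0:self.kt0 + len(self.group_names)] = kh
        gl, gh = self.opts.gain_bounds
        lo[self.g0:self.g0 + len(self.channels)] = gl
        hi[self.g0:self.g0 + len(self.channels)] = gh
        return Bounds(lo, hi)

    def initial_point(self, kt_init=None):
        """Rigid-tendon static-optimization warm start (deterministic)."""
        x0 = np.zeros(self.n_var)
        for b in self.blocks:
            a0 = np.zeros((b.K, self.nm))
            for k in range(b.K):
                lmw = np.sqrt(np.maximum(b.lmt[:, k] - b.lslack, 1e-6) ** 2
                              + (b.lopt * b.sina) ** 2) / b.lopt
                cosw = np.sqrt(np.maximum(lmw**2 - b.sina**2, 1e-9)) / lmw
                fl = active_force_length(lmw, self.constants)
                fp, _ = _passive_raw(lmw, b.kpe, b.s0, b.sm)
                gain = b.R[:, :, k].T * (b.fmax * fl * cosw)      # (nd, nm)
                tau_act = b.tau[:, k] - b.R[:, :, k].T @ (b.fmax * np.maximum(fp, 0) * cosw)
                a0[k], _ = static_optimize(gain, tau_act, w_reserve=900.0,
                                           tau_scale=b.tau_scale)
            a0 = np.clip(a0, 1e-3, 1.0)
            # compliant-equilibrium fiber lengths at the warm-start activations
            lm0 = np.zeros((b.K, self.nm))
            for m, p in enumerate(self.muscles):
                for k in range(b.K):
                    try:
                        r = solve_fiber_equilibrium(
                            b.lmt[m, k], float(a0[k, m]), p, "compliant",
                            constants=self.constants)
                        lm0[k, m] = r.lm_norm
                    except RuntimeError:
                        lm0[k, m] = max((b.lmt[m, k] - p.l_slack) / p.l_opt, 0.5)
            lm0 = np.clip(lm0, 0.31, 1.89)
            vm0 = np.zeros_like(lm0)
            vm0[1:] = np.diff(lm0, axis=0) / b.h[:, None] / b.vmax[None, :]
            vm0 = np.clip(vm0, -0.9, 0.9)
            x0[b.ia] = a0
            x0[b.ilm] = lm0
            x0[b.ivm] = vm0
            x0[b.ie] = a0
            x0[b.ires] = 0.0
        if self.group_names:
            if kt_init is None:
                kt_init = [self.constants.k_t_generic] * len(self.group_names)
            x0[self.kt0:self.kt0 + len(self.group_names)] = np.clip(
                kt_init, *self.opts.kt_bounds)
        if self.channels:
            x0[self.g0:self.g0 + len(self.channels)] = 1.0
        return x0

    # ---------------- objective ----------------
    def objective(self, x):
        o = self.opts
        J = 0.0
        for b in self.blocks:
            J += self.w_eff * np.sum(b.wq[:, None] * x[b.ia] ** 2)
            J += o.w_reserve * np.sum(b.wq[:, None] * x[b.ires] ** 2)
            J += o.w_velocity * np.sum(b.wq[:, None] * x[b.ivm] ** 2)
        return J

    def gradient(self, x):
        o = self.opts
        g = np.zeros(self.n_var)
        for b in self.blocks:
            g[b.ia] = 2.0 * self.w_eff * b.wq[:, None] * x[b.ia]
            g[b.ires] = 2.0 * o.w_reserve * b.wq[:, None] * x[b.ires]
            g[b.ivm] = 2.0 * o.w_velocity * b.wq[:, None] * x[b.ivm]
        return g

    def hessian(self, x):
        o = self.opts
        d = np.zeros(self.n_var)
        for b in self.blocks:
            d[b.ia] = 2.0 * self.w_eff * b.wq[:, None] * np.ones_like(x[b.ia])
            d[b.ires] = 2.0 * o.w_reserve * b.wq[:, None] * np.ones_like(x[b.ires])
            d[b.ivm] = 2.0 * o.w_velocity * b.wq[:, None] * np.ones_like(x[b.ivm])
        return sp.diags(d).tocsr()

    # ---------------- muscle-level quantities on the mesh ----------------
    def _muscle_eval(self, x, b: _TrialBlock):
        a = x[b.ia]
        lm = x[b.ilm]
        vm = x[b.ivm]
        kt_m = b.kt_fixed.copy()
        free = self.muscle_group >= 0
        if np.any(free):
            kt_m = np.where(free, x[self.kt0 + np.maximum(self.muscle_group, 0)], kt_m)
        fl, dfl = active_force_length(lm, self.constants, deriv=True)
        fv, dfv = force_velocity(vm, self.constants, deriv=True)
        fp, dfp = _passive_raw(lm, b.kpe, b.s0, b.sm)
        s2 = b.sina**2
        root = np.sqrt(np.maximum(lm**2 - s2, 1e-9))
        cosa = root / lm
        dcosa = s2 / (lm**2 * root)
        proj = b.lopt * root                       # projected fiber length, m
        lt = (b.lmt.T - proj) / b.lslack
        dlt_dlm = -(b.lopt * lm / root) / b.lslack
        ft, dft_dlt, dft_dkt = tendon_force(lt, kt_m, self.constants,
                                            clamp=False, deriv=True)
        fm_n = a * fl * fv + fp + FIBER_DAMPING * vm
        return dict(a=a, lm=lm, vm=vm, fl=fl, dfl=dfl, fv=fv, dfv=dfv, fp=fp,
                    dfp=dfp, cosa=cosa, dcosa=dcosa, lt=lt, dlt=dlt_dlm,
                    ft=ft, dft_dlt=dft_dlt, dft_dkt=dft_dkt, fm_n=fm_n,
                    kt_m=kt_m)

    # ---------------- constraints ----------------
    def constraints(self, x):
        o = self.opts
        c = np.zeros(self.n_con)
        for b in self.blocks:
            q = self._muscle_eval(x, b)
            # fiber-tendon equilibrium, normalized by fmax
            phi = q["fm_n"] * q["cosa"] - q["ft"]
            c[b.r_eq:b.r_eq + b.K * self.nm] = phi.ravel()
            # activation dynamics (backward Euler)
            a, e = q["a"], x[b.ie]
            rate = activation_dynamics_rate(e[1:], a[1:], o.tau_act, o.tau_deact)
            c[b.r_act:b.r_act + (b.K - 1) * self.nm] = (
                a[1:] - a[:-1] - b.h[:, None] * rate).ravel()
            # fiber-length dynamics
            lm, vm = q["lm"], q["vm"]
            c[b.r_fib:b.r_fib + (b.K - 1) * self.nm] = (
                lm[1:] - lm[:-1] - b.h[:, None] * vm[1:] * b.vmax[None, :]).ravel()
            # moment balance per dof, normalized by tau_scale
            FT = (q["ft"] * b.fmax[None, :]).T          # (nm, K)
            mus = np.einsum("mdk,mk->dk", b.R, FT)
            res = x[b.ires].T                           # (nd, K)
            mom = (mus - b.tau) / b.tau_scale[:, None] + res
            c[b.r_mom:b.r_mom + b.K * b.nd] = mom.T.ravel()
            # periodic states
            c[b.r_per:b.r_per + self.nm] = a[-1] - a[0]
            c[b.r_per + self.nm:b.r_per + 2 * self.nm] = lm[-1] - lm[0]
        return c

    def jacobian(self, x):
        o = self.opts
        rows, cols, vals = [], [], []

        def add(r, cl, v):
            rows.append(np.asarray(r).ravel())
            cols.append(np.asarray(cl).ravel())
            vals.append(np.asarray(v).ravel())

        for b in self.blocks:
            q = self._muscle_eval(x, b)
            K, nm, nd = b.K, self.nm, b.nd
            req = b.r_eq + np.arange(K * nm).reshape(K, nm)
            # equilibrium partials
            dphi_da = q["fl"] * q["fv"] * q["cosa"]
            dphi_dlm = ((q["a"] * q["dfl"] * q["fv"] + q["dfp"]) * q["cosa"]
                        + q["fm_n"] * q["dcosa"] - q["dft_dlt"] * q["dlt"])
            dphi_dvm = (q["a"] * q["fl"] * q["dfv"] + FIBER_DAMPING) * q["cosa"]
            add(req, b.ia, dphi_da)
            add(req, b.ilm, dphi_dlm)
            add(req, b.ivm, dphi_dvm)
            free = self.muscle_group >= 0
            if np.any(free):
                gcol = self.kt0 + np.maximum(self.muscle_group, 0)
                mfree = np.where(free)[0]
                add(req[:, mfree],
                    np.broadcast_to(gcol[mfree], (K, mfree.size)),
                    -q["dft_dkt"][:, mfree])
            # activation dynamics
            ract = b.r_act + np.arange((K - 1) * nm).reshape(K - 1, nm)
            _, d_de, d_da = activation_dynamics_rate(
                x[b.ie][1:], q["a"][1:], o.tau_act, o.tau_deact, deriv=True)
            h = b.h[:, None]
            add(ract, b.ia[1:], 1.0 - h * d_da)
            add(ract, b.ia[:-1], -np.ones_like(h * d_da))
            add(ract, b.ie[1:], -h * d_de)
            # fiber dynamics
            rfib = b.r_fib + np.arange((K - 1) * nm).reshape(K - 1, nm)
            add(rfib, b.ilm[1:], np.ones((K - 1, nm)))
            add(rfib, b.ilm[:-1], -np.ones((K - 1, nm)))
            add(rfib, b.ivm[1:], -h * np.broadcast_to(b.vmax, (K - 1, nm)))
            # moment balance
            dFT_dlm = (q["dft_dlt"] * q["dlt"]) * b.fmax[None, :]     # (K, nm)
            for d in range(nd):
                rmom = b.r_mom + np.arange(K) * nd + d
                for m in b.span[d]:
                    add(rmom, b.ilm[:, m],
                        b.R[m, d] * dFT_dlm[:, m] / b.tau_scale[d])
                    if free[m]:
                        add(rmom,
                            np.full(K, self.kt0 + self.muscle_group[m]),
                            b.R[m, d] * q["dft_dkt"][:, m] * b.fmax[m]
                            / b.tau_scale[d])
                add(rmom, b.ires[:, d], np.ones(K))
            # periodicity
            rper = b.r_per + np.arange(nm)
            add(rper, b.ia[-1], np.ones(nm))
            add(rper, b.ia[0], -np.ones(nm))
            add(rper + nm, b.ilm[-1], np.ones(nm))
            add(rper + nm, b.ilm[0], -np.ones(nm))

        J = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_con, self.n_var),
        )
        return J.tocsr()

    def emg_linear_constraint(self):
        """Hard corridor |e - gain*envelope| <= bound for tracked channels."""
        if not self.channels:
            return None
        rows, cols, vals = [], [], []
        nrow = 0
        for b in self.blocks:
            for ci, ch in enumerate(self.channels):
                mname = self.emg_map[ch]
                if mname not in self.names or ch not in b.trial.emg:
                    raise KeyError(f"missing EMG channel or muscle for {ch!r}")
                m = self.names.index(mname)
                env = b.trial.emg[ch]
                r = nrow + np.arange(b.K)
                rows += [r, r]
                cols += [b.ie[:, m], np.full(b.K, self.g0 + ci)]
                vals += [np.ones(b.K), -env]
                nrow += b.K
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nrow, self.n_var)).tocsr()
        d = self.opts.emg_bound
        return LinearConstraint(A, -d, d)

    # ---------------- solve ----------------
    def solve(self, x0=None):
        o = self.opts
        if x0 is None:
            x0 = self.initial_point()
        cons = [NonlinearConstraint(self.constraints, 0.0, 0.0,
                                    jac=self.jacobian,
                                    hess=lambda x, v: sp.csr_matrix(
                                        (self.n_var, self.n_var)))]
        lc = self.emg_linear_constraint()
        if lc is not None:
            cons.append(lc)
        res = minimize(
            self.objective, x0, jac=self.gradient, hess=self.hessian,
            bounds=self.bounds(), constraints=cons, method="trust-constr",
            options=dict(maxiter=o.maxiter, gtol=o.gtol, xtol=o.xtol,
                         verbose=o.verbose),
        )
        if res.constr_violation > 1e-4:
            raise RuntimeError(
                f"redundancy NLP infeasible: max constraint violation "
                f"{res.constr_violation:.3e} (status {res.status})")
        return res

    def extract(self, res, b: _TrialBlock) -> RedundancySolution:
        x = res.x
        q = self._muscle_eval(x, b)
        kt = {g: float(x[self.kt0 + i]) for i, g in enumerate(self.group_names)}
        gains = {c: float(x[self.g0 + i]) for i, c in enumerate(self.channels)}
        obj = {
            "total": float(res.fun),
            "activation": float(self.w_eff
                                * np.sum(b.wq[:, None] * x[b.ia] ** 2)),
            "reserve": float(self.opts.w_reserve
                             * np.sum(b.wq[:, None] * x[b.ires] ** 2)),
        }
        sol = RedundancySolution(
            time=b.t.copy(), muscle_names=tuple(self.names),
            dofs=b.trial.dofs,
            excitation=x[b.ie].T.copy(), activation=q["a"].T.copy(),
            lm_norm=q["lm"].T.copy(), vm_norm=q["vm"].T.copy(),
            fiber_force=(q["fm_n"] * b.fmax[None, :]).T.copy(),
            ce_force=(q["a"] * q["fl"] * q["fv"] * b.fmax[None, :]).T.copy(),
            tendon_force=(q["ft"] * b.fmax[None, :]).T.copy(),
            reserve=(x[b.ires] * b.tau_scale[None, :]).T.copy(),
            objective=obj,
            status={"success": bool(res.status in (1, 2) or res.constr_violation < 1e-6),
                    "status": int(res.status),
                    "niter": int(res.niter),
                    "constr_violation": float(res.constr_violation)},
            kt=kt, emg_gains=gains, trial=b.trial,
        )
        sol._vmax = b.vmax.copy()
        return sol


def solve_redundancy(trial: GaitTrial, muscles, workflow: str = "GEN",
                     emg_map=None, tendon_groups=None,
                     opts: SolverOptions | None = None,
                     constants: CurveConstants = GENERIC_CURVES,
                     ) -> RedundancySolution:
    """Solve the redundancy problem for one gait cycle.

    ``workflow`` is one of GEN/PAS/TEN/EMG.  For TEN/EMG, ``tendon_groups``
    maps group names to member muscle names whose tendon stiffness factor is
    optimized (shared within the group).  For EMG, ``emg_map`` maps EMG
    channel names (keys of ``trial.emg``) to tracked muscle names.
    """
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}")
    opts = opts or SolverOptions()
    if workflow in ("GEN", "PAS"):
        tendon_groups, emg_map = None, None
    elif workflow == "TEN":
        emg_map = None
        if not tendon_groups:
            raise ValueError("TEN workflow requires tendon_groups")
    elif workflow == "EMG":
        if not emg_map:
            raise ValueError("EMG workflow requires an envelope-to-muscle map")
    prob = _Problem([trial], muscles, workflow, opts,
                    tendon_groups=tendon_groups, emg_map=emg_map,
                    constants=constants)
    res = prob.solve()
    return prob.extract(res, prob.blocks[0])


def personalize_tendon_stiffness(trials, muscles, tendon_groups,
                                 emg_map=None, opts: SolverOptions | None = None,
                                 constants: CurveConstants = GENERIC_CURVES):
    """Optimize one tendon stiffness factor per group using all gait cycles
    simultaneously; returns ({group: k_t}, [RedundancySolution per trial]).

    With ``emg_map`` the problem is the EMG workflow (tracked excitations);
    otherwise the TEN workflow (minimal effort).
    """
    opts = opts or SolverOptions()
    workflow = "EMG" if emg_map else "TEN"
    prob = _Problem(list(trials), muscles, workflow, opts,
                    tendon_groups=tendon_groups, emg_map=emg_map,
                    constants=constants)
    res = prob.solve()
    sols = [prob.extract(res, b) for b in prob.blocks]
    kt = dict(sols[0].kt)
    kl, kh = opts.kt_bounds
    for g, v in kt.items():
        if v <= kl + 1e-6 or v >= kh - 1e-6:
            sols[0].status.setdefault("warnings", []).append(
                f"tendon group {g!r} stiffness pinned at bound {v:.2f}")
    return kt, sols


def moment_balance_residual(solution: RedundancySolution, trial: GaitTrial):
    """Per-dof residual tau_ID - sum(r * F_T) - tau_reserve on the solution
    grid; returns (residual curves (nd, K), max-abs per dof)."""
    tr = trial.resample(solution.time)
    if tr.moments.shape[1] != solution.tendon_force.shape[1]:
        raise ValueError("solution and trial grids do not match")
    mus = np.einsum("mdk,mk->dk", tr.arms, solution.tendon_force)
    resid = tr.moments - mus - solution.reserve
    return resid, np.max(np.abs(resid), axis=1)
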