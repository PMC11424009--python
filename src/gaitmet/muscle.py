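"""Fiber-tendon equilibrium and activation dynamics.

The muscle-tendon unit is a Hill-type fiber (active + passive elements, with
a small damping term for numerical well-posedness) in series with an elastic
tendon.  Pennation follows the fixed-height assumption: the fiber's
transverse width l_opt*sin(alpha_opt) is constant, so
cos(alpha) = sqrt(l_M^2 - w^2) / l_M.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .curves import (
    CurveConstants,
    GENERIC_CURVES,
    active_force_length,
    force_velocity,
    passive_force_length,
    tendon_force,
)
from .params import MuscleTendonParams

__all__ = [
    "solve_fiber_equilibrium",
    "activation_dynamics_rate",
    "EquilibriumResult",
    "FIBER_DAMPING",
]

#: normalized damping coefficient on fiber velocity (force units of fmax)
FIBER_DAMPING = 0.01


@dataclass
class EquilibriumResult:
    lm_norm: float
    v_norm: float
    fiber_force: float
    tendon_force: float
    residual: float


def _rigid_lm_norm(l_mt, p: MuscleTendonParams):
    """Fiber length from geometry with an inextensible tendon."""
    proj = l_mt - p.l_slack
    w = p.pennation_width
    lm = np.sqrt(np.maximum(proj, 1e-9) ** 2 + w**2)
    return lm / p.l_opt


def normalized_tendon_length(l_mt, lm_norm, p: MuscleTendonParams):
    """l~T from the muscle-tendon length and the normalized fiber length."""
    lm = np.asarray(lm_norm) * p.l_opt
    w = p.pennation_width
    proj = np.sqrt(np.maximum(lm**2 - w**2, 1e-12))
    return (l_mt - proj) / p.l_slack


def solve_fiber_equilibrium(
    l_mt: float,
    activation: float,
    params: MuscleTendonParams,
    mode: str = "compliant",
    v_norm: float = 0.0,
    constants: CurveConstants = GENERIC_CURVES,
    tol: float = 1e-9,
) -> EquilibriumResult:
    """Solve the fiber-tendon force equilibrium at one instant.

    In ``rigid`` mode the fiber length follows from geometry
    (l_M cos(alpha) = l_MT - l_slack) and the tendon transmits the projected
    fiber force.  In ``compliant`` mode the normalized fiber length is found
    by a safeguarded scalar root-find on the Hill equilibrium
    F_M cos(alpha) = F_T; the residual tolerance is ``tol`` relative to fmax.
    """
    p = params
    if not np.isfinite(l_mt) or not np.isfinite(activation):
        raise ValueError("non-finite input")
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation outside [0, 1]")
    if l_mt <= 0.5 * p.l_slack:
        raise ValueError("muscle-tendon length implausibly short")

    a = activation
    fl_fv = lambda lm: a * active_force_length(lm, constants) * force_velocity(
        v_norm, constants
    )

    if mode == "rigid":
        lm_n = float(_rigid_lm_norm(l_mt, p))
        cosa = float(p.cos_pennation(lm_n))
        fm = p.fmax * (
            fl_fv(lm_n) + passive_force_length(lm_n, p.k_pe, p.s0, p.s_m)
        )
        return EquilibriumResult(lm_n, v_norm, float(fm), float(fm * cosa), 0.0)
    if mode != "compliant":
        raise ValueError(f"unknown mode {mode!r}")

    def residual(lm_n):
        cosa = p.cos_pennation(lm_n)
        fm_n = (
            fl_fv(lm_n)
            + passive_force_length(lm_n, p.k_pe, p.s0, p.s_m, clamp=False)
            + FIBER_DAMPING * v_norm
        )
        lt_n = normalized_tendon_length(l_mt, lm_n, p)
        ft_n = tendon_force(lt_n, p.k_t, constants, clamp=False)
        return fm_n * cosa - ft_n

    lo, hi = 0.2, 2.2
    rlo, rhi = residual(lo), residual(hi)
    # widen the bracket once if needed before declaring failure
    if rlo * rhi > 0:
        lo, hi = 0.05, 3.5
        rlo, rhi = residual(lo), residual(hi)
    if rlo * rhi > 0:
        raise RuntimeError(
            f"{p.name}: no equilibrium bracket for l_mt={l_mt:.4f}, a={a:.3f} "
            f"(residuals {rlo:.3e}, {rhi:.3e})"
        )
    lm_n = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
    cosa = float(p.cos_pennation(lm_n))
    lt_n = float(normalized_tendon_length(l_mt, lm_n, p))
    ft = p.fmax * float(tendon_force(lt_n, p.k_t, constants, clamp=False))
    fm = ft / cosa
    res = float(residual(lm_n)) * p.fmax
    if abs(res) > tol * p.fmax * 10:
        raise RuntimeError(f"{p.name}: equilibrium residual {res:.3e} above tolerance")
    return EquilibriumResult(float(lm_n), v_norm, fm, ft, res)


def activation_dynamics_rate(excitation, activation, tau_act=0.015,
                             tau_deact=0.060, blend=10.0, deriv=False):
    """First-order activation dynamics da/dt, 1/s.

    Uses a smooth tanh blend between the activation and deactivation time
    constants so the rate is differentiable at e = a:
    da/dt = (e - a) * [ f/tau_act + (1-f)/tau_deact ],
    f = 0.5 + 0.5 tanh(blend*(e - a)).
    """
    if tau_act <= 0 or tau_deact <= 0:
        raise ValueError("time constants must be positive")
    e = np.asarray(excitation, dtype=float)
    a = np.asarray(activation, dtype=float)
    d = e - a
    t = np.tanh(blend * d)
    f = 0.5 + 0.5 * t
    rate_coef = f / tau_act + (1.0 - f) / tau_deact
    dadt = d * rate_coef
    if deriv:
        dcoef = 0.5 * blend * (1.0 - t**2) * (1.0 / tau_act - 1.0 / tau_deact)
        d_de = rate_coef + d * dcoef
        d_da = -rate_coef - d * dcoef
        return dadt, d_de, d_da
    return dadt
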