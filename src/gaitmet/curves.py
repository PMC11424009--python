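"""Normalized Hill-type muscle-tendon characteristic curves.

Functional forms follow the smooth formulation common in direct-collocation
muscle simulation: a three-Gaussian active force-length curve, a
log-hyperbolic force-velocity curve with an eccentric plateau, an exponential
passive force-length curve, and an exponential tendon force-length curve with
an adjustable stiffness (shape) factor.  All curves are dimensionless; force
multipliers scale the maximum isometric force.

The force-velocity curve is affinely renormalized so that f_v(0) = 1 and
f_v(-1) = 0 hold exactly (the raw cited constants give f_v(0) ~ 1.002 and
f_v(-1) ~ 0.012).

Every curve has an analytic derivative used by the redundancy NLP.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurveConstants",
    "GENERIC_CURVES",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "tendon_force",
    "eval_passive_force",
    "eval_contraction_curves",
]

# active force-length Gaussian coefficients (b1, b2, b3, b4) per term;
# the first center is nudged (-0.01) so the summed curve peaks at l~M = 1
_AFL = np.array(
    [
        [0.8150671134243542, 1.045033428970575, 0.162384573599574, 0.0633034484654646],
        [0.433004984392647, 0.716775413397760, -0.0299471169706956, 0.2004475753188907],
        [0.1, 1.0, 0.353553390593274, 0.0],
    ]
)

# raw force-velocity coefficients (d1..d4) of the log-hyperbolic form
_FV = (-0.3183098861837907, -8.149, -0.374, 0.8860)


@dataclass
class CurveConstants:
    """Constants of the generic normalized curves.

    ``c1, c2, c3`` parameterize the exponential tendon curve
    ``f_t = c1 * exp(k_t * (lt - c2)) - c3 (+ shift)``; ``k_t_generic`` is the
    generic tendon shape factor.  When a personalized ``k_t`` is used, the
    curve is shifted so its value at the slack-normalized length lt = 1 is
    unchanged from the generic curve (the personalization knob changes the
    stiffness, not the resting offset).
    """

    active_fl: np.ndarray = field(default_factory=lambda: _AFL.copy())
    fv: tuple = _FV
    c1: float = 0.2
    c2: float = 0.995
    c3: float = 0.25
    k_t_generic: float = 35.0
    k_t_bounds: tuple = (15.0, 45.0)

    @property
    def tendon_slack_value(self) -> float:
        """Designed tendon force multiplier at lt = 1 (generic curve)."""
        return self.c1 * np.exp(self.k_t_generic * (1.0 - self.c2)) - self.c3


GENERIC_CURVES = CurveConstants()


def _check_finite(x, name):
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite {name}")


def active_force_length(lm_norm, constants: CurveConstants = GENERIC_CURVES,
                        deriv: bool = False):
    """Active force-length multiplier f_l(l~M) (three-Gaussian form)."""
    lm = np.asarray(lm_norm, dtype=float)
    _check_finite(lm, "lm_norm")
    f = np.zeros_like(lm)
    df = np.zeros_like(lm)
    for b1, b2, b3, b4 in constants.active_fl:
        den = b3 + b4 * lm
        z = (lm - b2) / den
        g = b1 * np.exp(-0.5 * z**2)
        f = f + g
        if deriv:
            dz = (den - (lm - b2) * b4) / den**2
            df = df + g * (-z) * dz
    return (f, df) if deriv else f


def force_velocity(v_norm, constants: CurveConstants = GENERIC_CURVES,
                   deriv: bool = False):
    """Force-velocity multiplier f_v(v~M).

    ``v_norm`` is fiber velocity in optimal fiber lengths per second divided
    by vmax, with *positive = lengthening*; v_norm = -1 is maximal shortening.
    Renormalized so f_v(0) = 1 and f_v(-1) = 0 exactly.
    """
    v = np.asarray(v_norm, dtype=float)
    _check_finite(v, "v_norm")
    d1, d2, d3, d4 = constants.fv

    def raw(u):
        arg = d2 * u + d3
        return d1 * np.log(arg + np.sqrt(arg**2 + 1.0)) + d4

    g0 = raw(0.0)
    gm1 = raw(-1.0)
    scale = 1.0 / (g0 - gm1)
    f = (raw(v) - gm1) * scale
    if deriv:
        arg = d2 * v + d3
        df = scale * d1 * d2 / np.sqrt(arg**2 + 1.0)
        return f, df
    return f


def passive_force_length(lm_norm, k_pe=4.0, s0=1.0, s_m=0.6,
                         clamp: bool = True, deriv: bool = False):
    """Passive force-length multiplier.

    f_pas(l~M) = (exp(k_pe (l~M - s0) / s_m) - 1) / (exp(k_pe) - 1),
    clamped at 0 below the onset length ``s0`` (negative passive force is
    nonphysical).  ``clamp=False`` returns the raw smooth expression (used
    inside the NLP, where a kink would hurt the optimizer; the raw curve is
    only slightly negative below s0).
    """
    lm = np.asarray(lm_norm, dtype=float)
    _check_finite(lm, "lm_norm")
    if np.any(lm <= 0):
        raise ValueError("lm_norm must be positive")
    den = np.expm1(k_pe)
    ex = np.exp(k_pe * (lm - s0) / s_m)
    f = (ex - 1.0) / den
    df = ex * (k_pe / s_m) / den
    if clamp:
        neg = f < 0.0
        f = np.where(neg, 0.0, f)
        df = np.where(neg, 0.0, df)
    return (f, df) if deriv else f


# alias matching the operation-level name
def eval_passive_force(lm_norm, params) -> np.ndarray:
    """Passive force multiplier for a MuscleTendonParams (clamped at 0)."""
    return passive_force_length(lm_norm, params.k_pe, params.s0, params.s_m)


def tendon_shift(k_t, constants: CurveConstants = GENERIC_CURVES):
    """Offset keeping f_t(lt=1) equal to the generic curve's value when the
    stiffness factor is personalized away from ``k_t_generic``."""
    c1, c2 = constants.c1, constants.c2
    return c1 * np.exp(constants.k_t_generic * (1.0 - c2)) - c1 * np.exp(
        np.asarray(k_t, dtype=float) * (1.0 - c2)
    )


def tendon_force(lt_norm, k_t=None, constants: CurveConstants = GENERIC_CURVES,
                 clamp: bool = True, deriv: bool = False):
    """Tendon force multiplier f_t(l~T; k_t).

    Exponential curve, strictly increasing in l~T; ``clamp=True`` floors the
    multiplier at 0 (a buckled tendon transmits no force).  ``deriv=True``
    additionally returns (d f_t / d lt, d f_t / d k_t) of the unclamped curve.
    """
    lt = np.asarray(lt_norm, dtype=float)
    _check_finite(lt, "lt_norm")
    if k_t is None:
        k_t = constants.k_t_generic
    k_t = np.asarray(k_t, dtype=float)
    c1, c2, c3 = constants.c1, constants.c2, constants.c3
    e = c1 * np.exp(k_t * (lt - c2))
    f = e - c3 + tendon_shift(k_t, constants)
    if deriv:
        dlt = e * k_t
        e1 = c1 * np.exp(k_t * (1.0 - c2))
        dkt = e * (lt - c2) - e1 * (1.0 - c2)
        if clamp:
            neg = f < 0
            return np.where(neg, 0.0, f), np.where(neg, 0.0, dlt), np.where(neg, 0.0, dkt)
        return f, dlt, dkt
    return np.maximum(f, 0.0) if clamp else f


def eval_contraction_curves(lm_norm, v_norm, constants: CurveConstants = GENERIC_CURVES,
                            lt_norm=1.0, k_t=None):
    """Evaluate (f_l, f_v, f_t) at the given normalized states.

    ``v_norm`` is normalized by vmax (positive lengthening); ``lt_norm`` is
    tendon length over slack length.
    """
    if np.any(np.asarray(lt_norm) <= 0):
        raise ValueError("normalized tendon length must be positive")
    fl = active_force_length(lm_norm, constants)
    fv = force_velocity(v_norm, constants)
    ft = tendon_force(lt_norm, k_t, constants)
    return fl, np.maximum(fv, 0.0), ft
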