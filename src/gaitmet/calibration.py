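"""Calibration of passive force-length parameters against passive joint
moment-angle targets.

The passive moment produced at a joint in a quasi-static posture sweep is
simulated with zero activation and a rigid tendon; the exponential
passive-curve parameters (k_pe, s0) are then adjusted — shared within
functional muscle groups — so the simulated curves match experimental
targets in a least-squares sense.  The passive strain span s_m stays fixed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .curves import passive_force_length
from .params import MuscleTendonParams
from .trial import Geometry

__all__ = [
    "PassiveMomentTarget",
    "simulate_passive_joint_moment",
    "calibrate_passive_params",
    "CalibrationReport",
]


@dataclass
class PassiveMomentTarget:
    """Experimental passive moment-angle curve for one joint/posture."""

    joint: str
    angles: np.ndarray          # rad, strictly increasing
    moments: np.ndarray         # N*m
    posture: dict = field(default_factory=dict)  # other joints' fixed angles
    sign_convention: str = ""

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angle grid must be strictly increasing")
        if not np.all(np.isfinite(self.moments)):
            raise ValueError("target moments must be finite")


def _rigid_lm_norm(lmt, p: MuscleTendonParams):
    w = p.pennation_width
    proj = np.maximum(lmt - p.l_slack, 1e-9)
    return np.sqrt(proj**2 + w**2) / p.l_opt


def simulate_passive_joint_moment(angles, joint, geometry: Geometry, muscles,
                                  posture=None):
    """Passive (zero-activation) joint moment over an angle sweep, N*m.

    Rigid-tendon resolution: moment(q) = sum over muscles of
    r(q) * fmax * f_pas(l~M(q)) * cos(pennation).
    """
    posture = dict(posture or {})
    angles = np.asarray(angles, dtype=float)
    moment = np.zeros_like(angles)
    touched = False
    for p in muscles:
        if joint not in geometry.spanned(p.name):
            continue
        touched = True
        q = {d: np.full_like(angles, posture.get(d, 0.0))
             for d in geometry.spanned(p.name)}
        q[joint] = angles
        lmt = geometry.mtu_length(p.name, q)
        lm = _rigid_lm_norm(lmt, p)
        fp = passive_force_length(lm, p.k_pe, p.s0, p.s_m)
        cosa = p.cos_pennation(lm)
        moment = moment + geometry.moment_arm(p.name, joint, angles) \
            * p.fmax * fp * cosa
    if not touched:
        raise ValueError(f"no muscle in the set spans joint {joint!r}")
    return moment


@dataclass
class CalibrationReport:
    params: dict                # group -> (k_pe, s0)
    rmse_before: dict           # target index -> N*m
    rmse_after: dict
    n_starts: int
    best_cost: float


def _group_of(name, groups):
    for g, members in groups.items():
        if name in members:
            return g
    return None


def calibrate_passive_params(targets, geometry: Geometry, muscles,
                             groups=None, bounds=((1.0, 10.0), (0.8, 1.4)),
                             n_starts: int = 5, seed: int = 0):
    """Calibrate (k_pe, s0) per muscle group against passive moment targets.

    ``groups`` maps group name -> member muscle names; muscles not listed
    keep their generic parameters.  Default: one group per joint touched,
    containing every muscle spanning it.  Multi-start least squares (seeded)
    guards against local minima.

    Returns (calibrated muscle list, CalibrationReport).
    """
    if not targets:
        raise ValueError("at least one passive moment target required")
    if groups is None:
        joints = {t.joint for t in targets}
        groups = {
            j: [p.name for p in muscles if j in geometry.spanned(p.name)]
            for j in joints
        }
    group_names = list(groups)
    calibrated = {m for g in group_names for m in groups[g]}

    (k_lo, k_hi), (s_lo, s_hi) = bounds
    lo = np.array([k_lo, s_lo] * len(group_names))
    hi = np.array([k_hi, s_hi] * len(group_names))

    def apply(theta):
        out = []
        for p in muscles:
            g = _group_of(p.name, groups)
            if g is None:
                out.append(p)
            else:
                gi = group_names.index(g)
                out.append(replace(p, k_pe=float(theta[2 * gi]),
                                   s0=float(theta[2 * gi + 1])))
        return out

    def residuals(theta):
        ms = apply(theta)
        res = []
        for t in targets:
            sim = simulate_passive_joint_moment(
                t.angles, t.joint, geometry, ms, t.posture)
            res.append(sim - t.moments)
        return np.concatenate(res)

    def rmse_per_target(theta):
        ms = apply(theta)
        out = {}
        for i, t in enumerate(targets):
            sim = simulate_passive_joint_moment(
                t.angles, t.joint, geometry, ms, t.posture)
            out[i] = float(np.sqrt(np.mean((sim - t.moments) ** 2)))
        return out

    theta0 = np.concatenate([
        [next(p.k_pe for p in muscles if p.name in groups[g]),
         next(p.s0 for p in muscles if p.name in groups[g])]
        for g in group_names
    ])
    rmse_before = rmse_per_target(theta0)

    rng = np.random.default_rng(seed)
    starts = [np.clip(theta0, lo, hi)]
    for _ in range(n_starts - 1):
        starts.append(lo + (hi - lo) * rng.random(lo.size))

    best = None
    for x0 in starts:
        try:
            fit = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None:
        raise RuntimeError("passive calibration failed from every start")

    rmse_after = rmse_per_target(best.x)
    # least-squares refinement cannot worsen the initial objective
    if sum(r**2 for r in rmse_after.values()) > sum(
            r**2 for r in rmse_before.values()) + 1e-12:
        best_x = np.clip(theta0, lo, hi)
    else:
        best_x = best.x
    report = CalibrationReport(
        params={g: (float(best_x[2 * i]), float(best_x[2 * i + 1]))
                for i, g in enumerate(group_names)},
        rmse_before=rmse_before, rmse_after=rmse_per_target(best_x),
        n_starts=len(starts), best_cost=float(best.cost))
    return apply(best_x), report
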