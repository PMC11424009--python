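"""Whole-body, muscle-group, and gait-phase energy aggregation.

Per-muscle metabolic rate trajectories from one simulated leg are integrated
over the gait cycle, doubled to account for both legs, normalized by body
mass, and offset by a basal rate.  Biarticular muscles' rates are attributed
to the joints they span in proportion to the instantaneous absolute moment
arms; joint-attributed rates are pooled into functional groups.  The
experimental counterpart converts breath-by-breath gas exchange to metabolic
power with the Brockway equation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GasExchangeSeries",
    "EnergyReport",
    "brockway_rate",
    "representative_gas_value",
    "whole_body_average",
    "split_biarticular",
    "muscle_group_rates",
    "phase_relative_cost",
    "compute_max_isometric_force",
    "BROCKWAY_COEFS",
    "BASAL_RATE",
]

#: Brockway equation coefficients, J per mL O2 and per mL CO2
BROCKWAY_COEFS = (16.58, 4.51)
#: assumed basal metabolic rate, W/kg
BASAL_RATE = 1.2
#: linear whole-limb muscle volume regression: V [cm^3] = c0 * (m*h) + c1
VOLUME_REGRESSION = (47.0, 1285.0)
#: muscle density, kg/m^3
MUSCLE_DENSITY = 1059.7


@dataclass
class GasExchangeSeries:
    """Breath-by-breath gas exchange; times s, rates mL/min."""

    times: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breath times must be increasing")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise ValueError("gas rates must be non-negative")


@dataclass
class EnergyReport:
    """Aggregated energetics of one gait cycle (one model, one workflow)."""

    whole_body_rate: float          # W/kg, two legs + basal
    total_cycle_energy: float       # J/kg (muscular, two legs)
    group_rates: dict               # group -> average W/kg (two legs)
    group_shares: dict              # group -> % of muscular energy
    stance_share: float             # %
    swing_share: float              # %
    model: str = ""
    workflow: str = ""
    speed: float = float("nan")
    basal_rate: float = BASAL_RATE
    extras: dict = field(default_factory=dict)


def brockway_rate(vo2, vco2, coefs=BROCKWAY_COEFS):
    """Metabolic power (W) from VO2 and VCO2 in mL/s (STPD)."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas rates must be non-negative")
    return coefs[0] * vo2 + coefs[1] * vco2


def representative_gas_value(series: GasExchangeSeries, window: float = 180.0):
    """Mean (VO2, VCO2) in mL/s over the final ``window`` seconds."""
    t_end = series.times[-1]
    if t_end - series.times[0] < window:
        raise ValueError(f"series shorter than the {window:.0f}-s averaging window")
    sel = series.times > t_end - window
    return (float(np.mean(series.vo2[sel])) / 60.0,
            float(np.mean(series.vco2[sel])) / 60.0)


def whole_body_average(edot_total, time, body_mass, basal=BASAL_RATE):
    """Whole-body average rate, W/kg: (2 / T / m) * integral(sum Edot dt) + basal.

    ``edot_total`` is the summed one-leg muscle rate (W) on ``time``, or a
    (n_muscles, K) array which is summed over muscles first.
    """
    time = np.asarray(time, dtype=float)
    e = np.asarray(edot_total, dtype=float)
    if e.ndim == 2:
        e = e.sum(axis=0)
    T = time[-1] - time[0]
    if T <= 0 or body_mass <= 0:
        raise ValueError("cycle duration and body mass must be positive")
    energy = np.trapezoid(e, time)
    return 2.0 * energy / T / body_mass + basal


def split_biarticular(edot, arms, muscle_names, dofs, joints_spanned,
                      eps: float = 1e-6):
    """Attribute per-muscle rates to the joints spanned.

    At each instant a muscle's rate is apportioned to each spanned joint in
    proportion |r_joint| / sum(|r_spanned|); uniarticular muscles assign 100%
    to their joint.  Where all spanned arms are below ``eps`` the
    cycle-average ratio is used instead (flagged).

    Returns (attributed (nm, nd, K), flags dict).
    """
    edot = np.asarray(edot, dtype=float)
    arms = np.asarray(arms, dtype=float)
    nm, K = edot.shape
    nd = len(dofs)
    out = np.zeros((nm, nd, K))
    flags = {}
    for i, name in enumerate(muscle_names):
        spanned = [dofs.index(j) for j in joints_spanned[name]]
        if not spanned:
            raise ValueError(f"{name}: no joints spanned")
        absr = np.abs(arms[i, spanned, :])              # (ns, K)
        tot = absr.sum(axis=0)
        degenerate = tot < eps
        w = np.empty_like(absr)
        ok = ~degenerate
        w[:, ok] = absr[:, ok] / tot[ok]
        if np.any(degenerate):
            mean_r = np.mean(absr, axis=1)
            mean_w = mean_r / max(mean_r.sum(), eps)
            w[:, degenerate] = mean_w[:, None]
            flags[name] = int(np.sum(degenerate))
        for sj, j in enumerate(spanned):
            out[i, j] = w[sj] * edot[i]
    return out, flags


def muscle_group_rates(attributed, time, muscle_names, dofs, group_map,
                       body_mass=None):
    """Pool joint-attributed rates into functional groups.

    ``group_map`` maps (muscle, dof) -> group name and must cover every
    (muscle, dof) pair with nonzero attribution.  Returns (group series dict
    (W or W/kg), group shares dict (% of total cycle energy)).
    """
    attributed = np.asarray(attributed, dtype=float)
    series = {}
    for i, name in enumerate(muscle_names):
        for j, dof in enumerate(dofs):
            if not np.any(attributed[i, j] != 0):
                continue
            g = group_map.get((name, dof))
            if g is None:
                raise KeyError(f"({name}, {dof}) missing from the group map")
            series.setdefault(g, np.zeros(attributed.shape[2]))
            series[g] = series[g] + attributed[i, j]
    energies = {g: np.trapezoid(v, time) for g, v in series.items()}
    total = sum(energies.values())
    shares = {g: 100.0 * e / total if total > 0 else 0.0
              for g, e in energies.items()}
    if body_mass:
        series = {g: v * 2.0 / body_mass for g, v in series.items()}
    return series, shares


def phase_relative_cost(edot_total, time, events):
    """Relative cost (%) of stance (contact to toe-off) and swing phases."""
    time = np.asarray(time, dtype=float)
    e = np.asarray(edot_total, dtype=float)
    if e.ndim == 2:
        e = e.sum(axis=0)
    to = events.toe_off
    ic = events.initial_contact
    if not (time[0] <= ic < to < time[-1]):
        raise ValueError("degenerate gait phase")
    # split the grid at toe-off with an interpolated sample
    e_to = np.interp(to, time, e)
    pre = time <= to
    t_st = np.concatenate([time[pre], [to]])
    e_st = np.concatenate([e[pre], [e_to]])
    t_sw = np.concatenate([[to], time[~pre]])
    e_sw = np.concatenate([[e_to], e[~pre]])
    E_st = np.trapezoid(e_st, t_st)
    E_sw = np.trapezoid(e_sw, t_sw)
    total = E_st + E_sw
    if total <= 0:
        # a zero-energy cycle has no defined phase split
        return float("nan"), float("nan")
    return 100.0 * E_st / total, 100.0 * E_sw / total


def compute_max_isometric_force(body_mass, height, fraction_table,
                                specific_tension=35.0, l_opt=None,
                                regression=VOLUME_REGRESSION,
                                density=MUSCLE_DENSITY):
    """Anthropometric strength scaling.

    Total limb muscle volume follows the linear regression
    V[cm^3] = c0 * (mass[kg] * height[m]) + c1; per-muscle volume is the
    table fraction of the total; PCSA = volume / optimal fiber length; fmax =
    specific tension [N/cm^2] * PCSA; muscle mass = volume * density.

    Returns {muscle: {"fmax" N, "volume" cm^3, "mass" kg, "pcsa" cm^2}}.
    """
    if body_mass <= 0 or height <= 0:
        raise ValueError("anthropometry must be positive")
    fsum = sum(fraction_table.values())
    if abs(fsum - 1.0) > 1e-6:
        raise ValueError(f"volume fractions sum to {fsum}, expected 1")
    if l_opt is None:
        raise ValueError("l_opt table required")
    v_total = regression[0] * body_mass * height + regression[1]   # cm^3
    out = {}
    for name, frac in fraction_table.items():
        v = frac * v_total
        lo_cm = l_opt[name] * 100.0
        pcsa = v / lo_cm
        out[name] = {
            "fmax": specific_tension * pcsa,
            "volume": v,
            "mass": v * 1e-6 * density,
            "pcsa": pcsa,
        }
    return out


def energy_report(edot, time, arms, muscle_names, dofs, joints_spanned,
                  group_map, events, body_mass, basal=BASAL_RATE,
                  model="", workflow="", speed=float("nan")) -> EnergyReport:
    """Convenience: full aggregation of one metabolic trajectory set."""
    wb = whole_body_average(edot, time, body_mass, basal)
    attributed, flags = split_biarticular(edot, arms, muscle_names, dofs,
                                          joints_spanned)
    series, shares = muscle_group_rates(attributed, time, muscle_names, dofs,
                                        group_map)
    T = time[-1] - time[0]
    group_rates = {g: 2.0 * np.trapezoid(v, time) / T / body_mass
                   for g, v in series.items()}
    st, sw = phase_relative_cost(edot, time, events)
    total_e = 2.0 * np.trapezoid(np.asarray(edot).sum(axis=0), time) / body_mass
    return EnergyReport(
        whole_body_rate=float(wb), total_cycle_energy=float(total_e),
        group_rates=group_rates, group_shares=shares,
        stance_share=float(st), swing_share=float(sw),
        model=model, workflow=workflow, speed=speed, basal_rate=basal,
        extras={"attribution_flags": flags},
    )
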