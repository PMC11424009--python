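"""Six muscle metabolic energy models with the negative-rate modification.

Every model decomposes the muscle metabolic rate as

    Edot = Wdot_CE + Hdot_A + Hdot_M + Hdot_SL

(contractile-element work rate plus activation, maintenance, and
shortening/lengthening heat rates).  Model identifiers:

- UM03 : Umberger-family original (full work accounting, lengthening heat);
- UM10 : revision counting only concentric CE work, zero lengthening heat;
- UC16 : UM03-style accounting with orderly fiber-type recruitment and a
  non-negativity clamp on the total rate;
- BH04 : Bhargava-style separate activation/maintenance heats with
  force-based shortening/lengthening heat;
- HO06 : Hill-initial-heat style model, zero eccentric heat;
- LW07 : mass-free Hill-type model; half of eccentric CE work is dissipated
  as heat, so net negative rates are possible.

For BH04, HO06, and UM03 the shortening/lengthening heat is replaced, at any
instant where the total would be negative, by the value that makes the total
exactly zero (negative rate dissipated as heat); UC16 applies the same clamp
as part of its own definition.

Sign convention: normalized fiber velocity is positive when lengthening, so
Wdot_CE = -F_CE * v_M is positive during shortening.  Coefficients live in
``data/metabolic_constants.yaml`` (see its provenance comments).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .curves import GENERIC_CURVES, active_force_length, force_velocity

__all__ = [
    "MODEL_IDS",
    "load_model_constants",
    "MetabolicTrajectory",
    "compute_metabolic_rates",
    "apply_negative_rate_modification",
    "energy_efficiency",
    "characterize_model_surfaces",
]

MODEL_IDS = ("UM03", "BH04", "HO06", "LW07", "UM10", "UC16")

_constants_cache = None


def load_model_constants(model: str | None = None) -> dict:
    """Load the shipped per-model coefficient blocks (cached)."""
    global _constants_cache
    if _constants_cache is None:
        ref = importlib.resources.files("gaitmet.data") / "metabolic_constants.yaml"
        _constants_cache = yaml.safe_load(ref.read_text())
    if model is None:
        return _constants_cache
    if model not in _constants_cache:
        raise KeyError(f"unknown metabolic model {model!r}")
    return _constants_cache[model]


@dataclass
class MetabolicTrajectory:
    """Per-muscle metabolic rate decomposition for one model.

    All arrays are (n_muscles, K) in W.  For models with a single combined
    activation+maintenance expression the combined term is stored in
    ``hdot_a`` and ``hdot_m`` is zero.  ``modified`` flags instants where the
    negative-rate modification (or the UC16 clamp) fired.
    """

    model: str
    muscle_names: tuple
    time: np.ndarray
    wdot_ce: np.ndarray
    hdot_a: np.ndarray
    hdot_m: np.ndarray
    hdot_sl: np.ndarray
    modified: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def edot(self) -> np.ndarray:
        return self.wdot_ce + self.hdot_a + self.hdot_m + self.hdot_sl

    def total(self) -> np.ndarray:
        """Summed rate over muscles, W."""
        return self.edot.sum(axis=0)


def apply_negative_rate_modification(w_ce, h_am, h_sl):
    """Replace the shortening/lengthening heat wherever the total rate would
    be negative: h_sl_mod = -w_ce - h_am, forcing Edot = 0."""
    w_ce = np.asarray(w_ce, dtype=float)
    h_am = np.asarray(h_am, dtype=float)
    h_sl = np.asarray(h_sl, dtype=float)
    neg = w_ce + h_am + h_sl < 0
    return np.where(neg, -w_ce - h_am, h_sl), neg


def energy_efficiency(w_ce, e_dot, floor: float = 1e-9):
    """Contractile-work-over-metabolic-rate efficiency, 0 where the rate is
    at or below ``floor``."""
    w_ce = np.asarray(w_ce, dtype=float)
    e_dot = np.asarray(e_dot, dtype=float)
    out = np.zeros(np.broadcast_shapes(w_ce.shape, e_dot.shape))
    ok = e_dot > floor
    out[ok] = (w_ce * np.ones_like(e_dot))[ok] / e_dot[ok]
    return out


def _recruited_fast_fraction(f_fast, A):
    """Orderly-recruitment effective fast-twitch fraction at intensity A."""
    s = np.sin(0.5 * np.pi * A)
    c = 1.0 - np.cos(0.5 * np.pi * A)
    num = f_fast * c
    den = (1.0 - f_fast) * s + f_fast * c
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    return out


def _bh_length_scaling(lm):
    """Piecewise fiber-length dependence of the maintenance heat."""
    lm = np.asarray(lm, dtype=float)
    return np.where(lm <= 0.5, 0.5,
                    np.where(lm <= 1.0, lm,
                             np.where(lm <= 1.5, -2.0 * lm + 3.0, 0.0)))


def _rates_one_muscle(model, c, e, a, lm, vm, p, constants=GENERIC_CURVES):
    """Rate components (W) for one muscle given its state trajectories.

    ``vm`` is fiber velocity normalized by vmax, positive = lengthening.
    Returns (w_ce, h_a, h_m, h_sl, modified_mask).
    """
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    lm = np.asarray(lm, dtype=float)
    vm = np.asarray(vm, dtype=float)
    fl = active_force_length(lm, constants)
    fv = np.maximum(force_velocity(vm, constants), 0.0)
    v_lopt = vm * p.vmax                       # optimal fiber lengths / s
    v_m = v_lopt * p.l_opt                     # m/s, + lengthening
    f_ce = a * fl * fv * p.fmax                # contractile element force, N
    f_iso = a * fl * p.fmax                    # isometric CE force at (a, l)
    w_ce = -f_ce * v_m                         # + during shortening
    mass = p.muscle_mass
    f_fast = 1.0 - p.slow_twitch_fraction
    shortening = v_lopt < 0

    fam = c["family"]
    if fam == "umberger":
        A = np.where(e > a, e, 0.5 * (e + a))
        if c["orderly_recruitment"]:
            f_fast_eff = _recruited_fast_fraction(f_fast, A)
        else:
            f_fast_eff = np.full_like(A, f_fast)
        S = c["aerobic_scale"]
        h_am = (c["h_am_fast"] * f_fast_eff + c["h_am_base"]) \
            * A ** c["activation_exponent_am"]
        long_fiber = lm > 1.0
        h_am = np.where(long_fiber, h_am * (0.4 + 0.6 * fl), h_am)
        vmax_slow = p.vmax / c["vmax_slow_divisor"]
        a_s_slow = c["alpha_short_slow_numerator"] / vmax_slow
        a_s_fast = c["alpha_short_fast_numerator"] / p.vmax
        alpha_s = a_s_slow * (1.0 - f_fast_eff) + a_s_fast * f_fast_eff
        h_short = -alpha_s * v_lopt * A ** c["activation_exponent_short"]
        alpha_l = c["alpha_length_factor"] * a_s_slow
        h_len = alpha_l * v_lopt * A ** c["activation_exponent_length"]
        if not c["lengthening_heat"]:
            h_len = np.zeros_like(h_len)
        h_sl = np.where(shortening, h_short, h_len)
        h_sl = np.where(long_fiber, h_sl * fl, h_sl)
        h_am = h_am * S * mass
        h_sl = h_sl * S * mass
        w = np.maximum(w_ce, 0.0) if c["concentric_work_only"] else w_ce
        h_a, h_m = h_am, np.zeros_like(h_am)
    elif fam == "bhargava":
        su = np.sin(0.5 * np.pi * e)
        cu = 1.0 - np.cos(0.5 * np.pi * e)
        sa = np.sin(0.5 * np.pi * a)
        ca = 1.0 - np.cos(0.5 * np.pi * a)
        f_slow = p.slow_twitch_fraction
        h_a = mass * (f_slow * c["activation_heat_slow"] * su
                      + f_fast * c["activation_heat_fast"] * cu)
        h_m = mass * _bh_length_scaling(lm) * (
            f_slow * c["maintenance_heat_slow"] * sa
            + f_fast * c["maintenance_heat_fast"] * ca)
        alpha = np.where(
            shortening,
            c["shortening_iso_coef"] * f_iso + c["shortening_ce_coef"] * f_ce,
            c["lengthening_ce_coef"] * f_ce)
        h_sl = -alpha * v_m          # + shortening, negative when lengthening
        w = w_ce
    elif fam == "houdijk":
        h_a = np.zeros_like(a)
        h_m = mass * c["maintenance_coef"] * a * fl \
            * (p.vmax / c["maintenance_vmax_ref"])
        h_sl = np.where(shortening, -c["shortening_iso_coef"] * f_iso * v_m, 0.0)
        w = w_ce
    elif fam == "lichtwark":
        # mass-free: heats expressed in units of F_max * l_opt
        h_a = np.zeros_like(a)
        h_m = c["maintenance_coef"] * a * fl * p.fmax * p.l_opt * p.vmax
        h_short = np.where(shortening, -c["shortening_coef"] * f_iso * v_m, 0.0)
        h_ecc = np.where(shortening, 0.0,
                         -c["eccentric_heat_work_fraction"] * w_ce)
        h_sl = h_short + h_ecc
        w = w_ce
    else:  # pragma: no cover
        raise ValueError(f"unknown model family {fam!r}")

    floor = c.get("heat_floor", 0.0) * (mass if c["mass_dependent"] else 0.0)
    if floor > 0:
        deficit = floor - (h_a + h_m + h_sl)
        bump = np.maximum(deficit, 0.0)
        h_m = h_m + bump             # keeps Edot = sum of components exact
    if c["negative_rate_modification"]:
        h_sl, modified = apply_negative_rate_modification(w, h_a + h_m, h_sl)
    else:
        modified = np.zeros_like(w, dtype=bool)
    return w, h_a, h_m, h_sl, modified


def compute_metabolic_rates(model: str, solution, muscles,
                            constants: dict | None = None,
                            curve_constants=GENERIC_CURVES) -> MetabolicTrajectory:
    """Metabolic rate trajectories of every muscle in a RedundancySolution."""
    c = constants or load_model_constants(model)
    if c["mass_dependent"]:
        for p in muscles:
            if not p.muscle_mass > 0:   # False for nan
                raise ValueError(f"{p.name}: muscle_mass required by {model}")
    nm, K = solution.activation.shape
    w = np.zeros((nm, K))
    ha = np.zeros((nm, K))
    hm = np.zeros((nm, K))
    hsl = np.zeros((nm, K))
    mod = np.zeros((nm, K), dtype=bool)
    for i, p in enumerate(muscles):
        w[i], ha[i], hm[i], hsl[i], mod[i] = _rates_one_muscle(
            model, c, solution.excitation[i], solution.activation[i],
            solution.lm_norm[i], solution.vm_norm[i], p, curve_constants)
    return MetabolicTrajectory(
        model=model, muscle_names=tuple(p.name for p in muscles),
        time=np.asarray(solution.time, dtype=float),
        wdot_ce=w, hdot_a=ha, hdot_m=hm, hdot_sl=hsl, modified=mod)


def characterize_model_surfaces(model: str, params, activations, lm_grid,
                                vm_grid, constants: dict | None = None,
                                curve_constants=GENERIC_CURVES):
    """Tabulate total rate and efficiency over (activation, l~M, v~M) grids.

    Excitation is taken equal to activation.  Returns dict with arrays of
    shape (n_a, n_l, n_v): ``edot`` (W) and ``efficiency``.
    """
    c = constants or load_model_constants(model)
    A, L, V = np.meshgrid(np.asarray(activations, dtype=float),
                          np.asarray(lm_grid, dtype=float),
                          np.asarray(vm_grid, dtype=float), indexing="ij")
    w, ha, hm, hsl, mod = _rates_one_muscle(
        model, c, A, A, L, V, params, curve_constants)
    edot = w + ha + hm + hsl
    return {"edot": edot, "wdot_ce": w, "hdot": ha + hm + hsl,
            "efficiency": energy_efficiency(w, edot), "modified": mod}
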