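"""Muscle-tendon parameter containers and their flat-table (CSV) serialization.

One row per muscle; column names match the dataclass field names exactly so a
parameter file can be audited and edited by hand.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MuscleTendonParams", "load_params", "save_params"]

#: density of mammalian skeletal muscle used to convert volume to mass, kg/m^3
MUSCLE_DENSITY = 1059.7


@dataclass
class MuscleTendonParams:
    """Architecture, passive-curve, and tendon-stiffness parameters of one
    muscle-tendon unit.

    Parameters
    ----------
    name : str
        Muscle identifier.
    fmax : float
        Maximum isometric force, N.
    l_opt : float
        Optimal fiber length, m.
    l_slack : float
        Tendon slack length, m.
    alpha_opt : float
        Pennation angle at optimal fiber length, rad.
    vmax : float
        Maximum shortening velocity, optimal fiber lengths / s.
    slow_twitch_fraction : float
        Fraction of slow-twitch fibers, in [0, 1].
    muscle_mass : float
        Muscle mass, kg (volume x density).  Required by all metabolic models
        except the mass-free LW07 formulation.
    k_pe : float
        Exponential shape factor of the passive force-length curve.
    s0 : float
        Normalized fiber length at which passive force starts to rise.
    s_m : float
        Normalized passive strain span from ``s0``-relative onset to the
        length (measured from optimal length) where passive force reaches
        the maximum isometric force.
    k_t : float
        Tendon force-length shape (stiffness) factor.
    joints_spanned : tuple of str
        Degrees of freedom this unit crosses.
    """

    name: str
    fmax: float
    l_opt: float
    l_slack: float
    alpha_opt: float = 0.0
    vmax: float = 10.0
    slow_twitch_fraction: float = 0.5
    muscle_mass: float = 0.1
    k_pe: float = 4.0
    s0: float = 1.0
    s_m: float = 0.6
    k_t: float = 35.0
    joints_spanned: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not (self.fmax > 0 and self.l_opt > 0 and self.l_slack >= 0):
            raise ValueError(
                f"{self.name}: fmax and l_opt must be positive, l_slack >= 0"
            )
        if not 0.0 <= self.slow_twitch_fraction <= 1.0:
            raise ValueError(f"{self.name}: slow_twitch_fraction outside [0, 1]")
        if not (self.s0 > 0 and self.s_m > 0 and self.k_pe > 0):
            raise ValueError(f"{self.name}: s0, s_m, k_pe must be positive")
        # nan is allowed (mass-free LW07 does not need it); metabolic models
        # that depend on mass reject it at evaluation time
        if not (np.isnan(self.muscle_mass) or self.muscle_mass > 0):
            raise ValueError(f"{self.name}: muscle_mass must be positive")
        if not 5.0 <= self.k_t <= 500.0:
            raise ValueError(f"{self.name}: k_t {self.k_t} outside sane bounds")
        self.joints_spanned = tuple(self.joints_spanned)

    @property
    def pennation_width(self) -> float:
        """Constant fiber-height of the fixed-width pennation model, m."""
        return self.l_opt * np.sin(self.alpha_opt)

    def cos_pennation(self, lm_norm):
        """cos(pennation) at normalized fiber length(s) ``lm_norm``."""
        lm_norm = np.asarray(lm_norm, dtype=float)
        s = np.sin(self.alpha_opt)
        return np.sqrt(np.maximum(lm_norm**2 - s**2, 1e-12)) / lm_norm


def save_params(muscles: Sequence[MuscleTendonParams], path) -> None:
    rows = []
    for m in muscles:
        d = asdict(m)
        d["joints_spanned"] = ";".join(m.joints_spanned)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_params(path) -> list[MuscleTendonParams]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        js = d.get("joints_spanned", "")
        d["joints_spanned"] = tuple(s for s in str(js).split(";") if s and s != "nan")
        out.append(MuscleTendonParams(**d))
    return out
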