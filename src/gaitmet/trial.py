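"""Gait-trial container and polynomial muscle-tendon geometry.

Geometry maps joint angles to muscle-tendon lengths and moment arms.  Moment
arms are per-dof polynomials r_j(q_j); muscle-tendon length is constructed as
l_MT(q) = l_ref - sum_j int r_j(q_j) dq_j, so r = -d l_MT / d q holds exactly
by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "GaitTrial", "GaitEvents"]


@dataclass
class Geometry:
    """Polynomial moment-arm geometry.

    ``arm_coefs[(muscle, dof)]`` holds polynomial coefficients (low order
    first) of the moment arm r(q_dof) in meters; ``l_ref[muscle]`` is the
    muscle-tendon length at the zero posture, m.
    """

    dofs: tuple
    muscles: tuple
    arm_coefs: dict
    l_ref: dict

    def spanned(self, muscle) -> tuple:
        return tuple(d for d in self.dofs if (muscle, d) in self.arm_coefs)

    def moment_arm(self, muscle, dof, q):
        """Moment arm of ``muscle`` about ``dof`` at angle(s) ``q``, m."""
        c = self.arm_coefs.get((muscle, dof))
        if c is None:
            return np.zeros_like(np.asarray(q, dtype=float))
        return np.polynomial.polynomial.polyval(np.asarray(q, dtype=float), c)

    def mtu_length(self, muscle, q: dict):
        """Muscle-tendon length at posture ``q`` ({dof: angle(s) rad}), m."""
        length = None
        for dof in self.spanned(muscle):
            c = np.asarray(self.arm_coefs[(muscle, dof)], dtype=float)
            # integral of the arm polynomial from 0 to q
            ci = np.concatenate([[0.0], c / np.arange(1, len(c) + 1)])
            contrib = np.polynomial.polynomial.polyval(
                np.asarray(q[dof], dtype=float), ci
            )
            length = contrib if length is None else length + contrib
        if length is None:
            raise KeyError(f"muscle {muscle!r} not in geometry")
        return self.l_ref[muscle] - length

    def mtu_velocity(self, muscle, q: dict, qdot: dict):
        """d l_MT / dt = -sum_j r_j(q_j) * qdot_j, m/s."""
        v = 0.0
        for dof in self.spanned(muscle):
            v = v - self.moment_arm(muscle, dof, q[dof]) * np.asarray(qdot[dof])
        return v


@dataclass
class GaitEvents:
    """Gait cycle events, s (cycle runs initial contact to next contact)."""

    initial_contact: float
    toe_off: float

    def validate(self, t0, t1):
        if not (t0 <= self.initial_contact < self.toe_off <= t1 + 1e-9):
            raise ValueError("events must lie within the cycle, toe-off after contact")


@dataclass
class GaitTrial:
    """One gait cycle's kinematics, kinetics, and muscle-tendon geometry.

    All time series share ``time``.  ``moments`` are inverse-dynamics joint
    moments (N*m); ``lmt`` muscle-tendon lengths (m) per muscle; ``arms``
    moment arms (m) with shape (n_muscles, n_dofs, n_time).
    """

    time: np.ndarray
    dofs: tuple
    muscle_names: tuple
    q: np.ndarray          # (n_dofs, n_time), rad
    qdot: np.ndarray       # (n_dofs, n_time), rad/s
    moments: np.ndarray    # (n_dofs, n_time), N*m
    lmt: np.ndarray        # (n_muscles, n_time), m
    arms: np.ndarray       # (n_muscles, n_dofs, n_time), m
    events: GaitEvents
    speed: float
    mass: float
    height: float
    emg: dict = field(default_factory=dict)   # channel -> envelope on `time`
    truth: dict = field(default_factory=dict) # ground-truth series, if synthetic

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        nt = self.time.size
        for name in ("q", "qdot", "moments"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.dofs), nt):
                raise ValueError(f"{name} shape {arr.shape} inconsistent with grid")
            setattr(self, name, arr)
        self.lmt = np.asarray(self.lmt, dtype=float)
        self.arms = np.asarray(self.arms, dtype=float)
        if self.lmt.shape != (len(self.muscle_names), nt):
            raise ValueError("lmt shape inconsistent")
        if self.arms.shape != (len(self.muscle_names), len(self.dofs), nt):
            raise ValueError("arms shape inconsistent")
        self.events.validate(self.time[0], self.time[-1])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def resample(self, time_new: np.ndarray) -> "GaitTrial":
        """Linear-interpolation resampling of every series to ``time_new``."""
        t = np.asarray(time_new, dtype=float)

        def interp(arr):
            return np.apply_along_axis(
                lambda y: np.interp(t, self.time, y), -1, arr
            )

        return GaitTrial(
            time=t, dofs=self.dofs, muscle_names=self.muscle_names,
            q=interp(self.q), qdot=interp(self.qdot), moments=interp(self.moments),
            lmt=interp(self.lmt), arms=interp(self.arms),
            events=self.events, speed=self.speed, mass=self.mass,
            height=self.height,
            emg={k: np.interp(t, self.time, v) for k, v in self.emg.items()},
            truth={k: interp(np.asarray(v)) for k, v in self.truth.items()},
        )
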