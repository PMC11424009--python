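"""Synthetic virtual subjects and gait trials with known ground truth.

The generator stands in for a motion-capture + spiroergometry experiment: it
produces one-leg gait cycles (smooth periodic kinematics, muscle-tendon
geometry consistent with moment arms by construction, inverse-dynamics
moments computed forward from ground-truth muscle forces so the redundancy
truth has zero reserves), EMG envelopes that are gain-scaled noisy copies of
the true excitations, and breath-by-breath gas exchange whose Brockway
energy matches a prescribed whole-body rate.

All randomness is drawn from numpy Generators seeded per component, so a
fixed seed reproduces a subject or trial bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .aggregation import GasExchangeSeries, compute_max_isometric_force
from .curves import (
    GENERIC_CURVES,
    active_force_length,
    force_velocity,
    passive_force_length,
    tendon_force,
)
from .muscle import activation_dynamics_rate
from .params import MuscleTendonParams
from .trial import GaitEvents, GaitTrial, Geometry

__all__ = [
    "VirtualSubject",
    "make_virtual_subject",
    "make_gait_trial",
    "process_emg",
    "make_emg_envelopes",
    "make_gas_exchange",
    "TENDON_GROUPS",
    "MUSCLE_GROUP_MAP",
]

DOFS = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion")

# nominal single-leg muscle set: (name, {dof: base moment arm m}, l_opt m,
# l_slack m, pennation rad, slow-twitch fraction, volume fraction)
_MUSCLE_TABLE = [
    ("iliopsoas",  {"hip_flexion": 0.040},                        0.11, 0.10, 0.14, 0.50, 0.10),
    ("glutmax",    {"hip_flexion": -0.055},                       0.15, 0.125, 0.17, 0.55, 0.18),
    ("hamstrings", {"hip_flexion": -0.055, "knee_flexion": 0.030}, 0.09, 0.33, 0.20, 0.55, 0.12),
    ("recfem",     {"hip_flexion": 0.040, "knee_flexion": -0.045}, 0.08, 0.33, 0.24, 0.40, 0.06),
    ("vasti",      {"knee_flexion": -0.045},                      0.09, 0.16, 0.26, 0.50, 0.20),
    ("bfsh",       {"knee_flexion": 0.028},                       0.11, 0.10, 0.21, 0.55, 0.04),
    ("gastroc",    {"knee_flexion": 0.018, "ankle_dorsiflexion": -0.050}, 0.055, 0.38, 0.25, 0.55, 0.10),
    ("soleus",     {"ankle_dorsiflexion": -0.050},                0.045, 0.27, 0.45, 0.80, 0.14),
    ("tibant",     {"ankle_dorsiflexion": 0.040},                 0.070, 0.22, 0.17, 0.70, 0.06),
]

#: tendon groups whose stiffness the TEN/EMG workflows personalize
TENDON_GROUPS = {
    "achilles": ["soleus", "gastroc"],
    "quadriceps": ["vasti", "recfem"],
}

#: (muscle, dof) -> functional group used in energy aggregation
MUSCLE_GROUP_MAP = {
    ("iliopsoas", "hip_flexion"): "hip flexors",
    ("glutmax", "hip_flexion"): "hip extensors",
    ("hamstrings", "hip_flexion"): "hip extensors",
    ("hamstrings", "knee_flexion"): "knee flexors",
    ("recfem", "hip_flexion"): "hip flexors",
    ("recfem", "knee_flexion"): "knee extensors",
    ("vasti", "knee_flexion"): "knee extensors",
    ("bfsh", "knee_flexion"): "knee flexors",
    ("gastroc", "knee_flexion"): "knee flexors",
    ("gastroc", "ankle_dorsiflexion"): "ankle plantarflexors",
    ("soleus", "ankle_dorsiflexion"): "ankle plantarflexors",
    ("tibant", "ankle_dorsiflexion"): "ankle dorsiflexors",
}

# excitation bump templates: muscle -> list of (center %cycle, width, amplitude)
_EXC_TEMPLATE = {
    "iliopsoas": [(0.62, 0.09, 0.28)],
    "glutmax": [(0.02, 0.10, 0.22)],
    "hamstrings": [(0.95, 0.09, 0.26)],
    "recfem": [(0.65, 0.08, 0.14), (0.08, 0.10, 0.08)],
    "vasti": [(0.08, 0.09, 0.30)],
    "bfsh": [(0.93, 0.08, 0.15)],
    "gastroc": [(0.45, 0.11, 0.33)],
    "soleus": [(0.45, 0.11, 0.40)],
    "tibant": [(0.02, 0.08, 0.26), (0.68, 0.11, 0.20)],
}


@dataclass
class VirtualSubject:
    """Ground-truth virtual subject: anthropometry, geometry, parameters."""

    mass: float
    height: float
    dofs: tuple
    muscles: list            # list[MuscleTendonParams] — ground truth
    geometry: Geometry
    seed: int
    speeds: tuple = (0.8, 1.25, 1.7)
    extras: dict = field(default_factory=dict)

    @property
    def muscle_names(self):
        return tuple(p.name for p in self.muscles)


def _cycle_duration(speed):
    return 1.05 * (1.25 / speed) ** 0.45


def _toe_off_fraction(speed):
    return float(np.clip(0.60 - 0.03 * (speed - 1.25), 0.55, 0.66))


def _kinematics(s, speed):
    """Joint-angle templates (rad) as truncated Fourier series of the cycle
    fraction s in [0, 1); periodic by construction."""
    A = 0.75 + 0.25 * speed / 1.25
    two = 2 * np.pi * s
    four = 4 * np.pi * s
    hip = 0.15 + 0.32 * A * np.cos(two + 0.25) + 0.03 * np.sin(four)
    knee = 0.38 - 0.22 * A * np.cos(two - 0.5) + 0.18 * A * np.cos(four - 2.5)
    ankle = 0.02 + 0.08 * A * np.sin(two + 2.2) + 0.07 * A * np.sin(four + 1.0)
    return {"hip_flexion": hip, "knee_flexion": knee, "ankle_dorsiflexion": ankle}


def _kinematics_dot(s, speed, T):
    A = 0.75 + 0.25 * speed / 1.25
    two = 2 * np.pi * s
    four = 4 * np.pi * s
    w1 = 2 * np.pi / T
    w2 = 4 * np.pi / T
    hip = -0.32 * A * w1 * np.sin(two + 0.25) + 0.03 * w2 * np.cos(four)
    knee = 0.22 * A * w1 * np.sin(two - 0.5) - 0.18 * A * w2 * np.sin(four - 2.5)
    ankle = 0.08 * A * w1 * np.cos(two + 2.2) + 0.07 * A * w2 * np.cos(four + 1.0)
    return {"hip_flexion": hip, "knee_flexion": knee, "ankle_dorsiflexion": ankle}


def make_virtual_subject(seed: int, n_muscles: int = 9,
                         speeds=(0.8, 1.25, 1.7),
                         mass: float = 71.3, height: float = 1.74,
                         specific_tension: float = 35.0) -> VirtualSubject:
    """Build a deterministic virtual subject.

    ``n_muscles`` selects the first n rows of the built-in muscle table but
    must keep every dof actuated by at least two muscles (9 = full set).
    Maximum isometric forces and masses come from the anthropometric volume
    regression; moment-arm polynomials get a seeded +/-10% jitter.
    """
    rng = np.random.default_rng(seed)
    table = _MUSCLE_TABLE[:n_muscles]
    used_dofs = set()
    for row in table:
        used_dofs |= set(row[1])
    counts = {d: sum(1 for row in table if d in row[1]) for d in used_dofs}
    if any(c < 2 for c in counts.values()):
        raise ValueError(f"every dof needs >= 2 muscles, got {counts}")

    fractions = {row[0]: row[6] for row in table}
    total = sum(fractions.values())
    fractions = {k: v / total for k, v in fractions.items()}
    lopts = {row[0]: row[2] for row in table}
    strengths = compute_max_isometric_force(
        mass, height, fractions, specific_tension, lopts)

    arm_coefs = {}
    muscles = []
    for name, arms, l_opt, l_slack, alpha, slow, _frac in table:
        jitter = 1.0 + 0.1 * (2 * rng.random() - 1.0)
        spans = tuple(arms)
        for dof, r0 in arms.items():
            slope = 0.15 * r0 * (2 * rng.random() - 1.0)
            arm_coefs[(name, dof)] = np.array([r0 * jitter, slope])
        muscles.append(MuscleTendonParams(
            name=name, fmax=strengths[name]["fmax"], l_opt=l_opt,
            l_slack=l_slack, alpha_opt=alpha, vmax=10.0,
            slow_twitch_fraction=slow, muscle_mass=strengths[name]["mass"],
            joints_spanned=spans,
        ))

    geom = Geometry(dofs=tuple(sorted(used_dofs, key=DOFS.index)),
                    muscles=tuple(p.name for p in muscles),
                    arm_coefs=arm_coefs, l_ref={})
    # reference lengths: mean muscle-tendon length over the preferred-speed
    # cycle sits at slack tendon + optimal fiber (taut, unloaded nominal)
    s = np.linspace(0, 1, 201)
    q = _kinematics(s, 1.25)
    for p in muscles:
        geom.l_ref[p.name] = 0.0
        delta = geom.mtu_length(p.name, q)      # = -integral term
        nominal = p.l_slack + p.l_opt * np.cos(p.alpha_opt)
        geom.l_ref[p.name] = nominal - float(np.mean(delta))

    return VirtualSubject(mass=mass, height=height, dofs=geom.dofs,
                          muscles=muscles, geometry=geom, seed=seed,
                          speeds=tuple(speeds))


def _periodic_bump(s, center, width, amp):
    # wrapped Gaussian bump on the unit circle
    d = (s - center + 0.5) % 1.0 - 0.5
    return amp * np.exp(-0.5 * (d / width) ** 2)


def _truth_excitations(subject: VirtualSubject, s, speed, rng):
    amp_scale = 0.7 + 0.3 * speed / 1.25
    exc = {}
    for p in subject.muscles:
        e = np.full_like(s, 0.02)
        for c, w, a in _EXC_TEMPLATE.get(p.name, []):
            c_j = c + 0.02 * (2 * rng.random() - 1.0)
            a_j = a * amp_scale * (1.0 + 0.15 * (2 * rng.random() - 1.0))
            e = e + _periodic_bump(s, c_j, w, a_j)
        exc[p.name] = np.clip(e, 0.0, 0.95)
    return exc


def make_gait_trial(subject: VirtualSubject, speed: float, seed: int,
                    mode: str = "open_loop", n_time: int = 301,
                    excitation_scale: float = 1.0,
                    constants=GENERIC_CURVES, solver_opts=None) -> GaitTrial:
    """Generate one ground-truth gait cycle at ``speed`` (m/s).

    ``mode='open_loop'``: excitations are smooth bump trains; states follow
    from forward integration of activation and fiber-contraction dynamics;
    joint moments are computed forward from the resulting tendon forces
    (zero-reserve truth).  ``mode='minimal'``: the open-loop trial is then
    re-solved with the minimal-effort redundancy formulation and the truth is
    replaced by that solution, guaranteeing the truth is itself the
    minimum-effort control (used by recovery experiments).
    """
    if not 0.5 <= speed <= 2.2:
        raise ValueError("speed outside generator range 0.5-2.2 m/s")
    rng = np.random.default_rng((seed, 1))
    T = _cycle_duration(speed)
    t = np.linspace(0.0, T, n_time)
    s = t / T
    q = _kinematics(s, speed)
    qdot = _kinematics_dot(s, speed, T)
    geom = subject.geometry
    names = subject.muscle_names
    nm = len(names)
    nd = len(geom.dofs)

    exc = _truth_excitations(subject, s, speed, rng)
    if excitation_scale != 1.0:
        exc = {k: excitation_scale * v for k, v in exc.items()}

    # activation dynamics, integrated over two cycles for periodicity
    act = {}
    for p in subject.muscles:
        e = exc[p.name]
        a = e[0]
        out = np.empty_like(e)
        for cycle in range(2):
            for i in range(n_time):
                out[i] = a
                if i < n_time - 1:
                    h = t[i + 1] - t[i]
                    k1 = activation_dynamics_rate(e[i], a)
                    k2 = activation_dynamics_rate(e[i + 1], a + h * k1)
                    a = np.clip(a + 0.5 * h * (k1 + k2), 0.0, 1.0)
        act[p.name] = out

    lmt = np.vstack([geom.mtu_length(n, q) for n in names])
    arms = np.zeros((nm, nd, n_time))
    for i, n in enumerate(names):
        for j, d in enumerate(geom.dofs):
            arms[i, j] = geom.moment_arm(n, d, q[d])

    # fiber states from a velocity-consistent equilibrium fixed point: solve
    # the Hill equilibrium per node, estimate fiber velocity by periodic
    # finite differences, re-solve including the velocity, iterate.  (The
    # lightly damped fiber ODE is numerically stiff; the muscle operates on
    # its equilibrium manifold at gait time scales.)
    from .muscle import solve_fiber_equilibrium

    lm = np.zeros((nm, n_time))
    vm = np.zeros((nm, n_time))
    for i, p in enumerate(subject.muscles):
        a_ser = act[p.name]
        v_est = np.zeros(n_time)
        for _ in range(4):
            for k in range(n_time):
                lm[i, k] = solve_fiber_equilibrium(
                    lmt[i, k], float(a_ser[k]), p, v_norm=float(v_est[k]),
                    constants=constants).lm_norm
            lm[i, -1] = lm[i, 0]            # periodic by construction
            grad = np.gradient(lm[i], t, edge_order=1)
            grad[0] = grad[-1] = (lm[i, 1] - lm[i, -2] + 0.0) / (
                (t[1] - t[0]) + (t[-1] - t[-2]))
            v_new = np.clip(grad / p.vmax, -1.0, 1.0)
            v_est = 0.5 * v_est + 0.5 * v_new
        vm[i] = v_est

    # tendon forces and forward moments
    ft = np.zeros((nm, n_time))
    for i, p in enumerate(subject.muscles):
        s2 = np.sin(p.alpha_opt) ** 2
        root = np.sqrt(np.maximum(lm[i] ** 2 - s2, 1e-9))
        lt = (lmt[i] - p.l_opt * root) / p.l_slack
        ft[i] = p.fmax * tendon_force(lt, p.k_t, constants, clamp=False)
    moments = np.einsum("mdk,mk->dk", arms, ft)

    events = GaitEvents(0.0, _toe_off_fraction(speed) * T)
    trial = GaitTrial(
        time=t, dofs=geom.dofs, muscle_names=names, q=np.vstack([q[d] for d in geom.dofs]),
        qdot=np.vstack([qdot[d] for d in geom.dofs]), moments=moments,
        lmt=lmt, arms=arms, events=events, speed=speed,
        mass=subject.mass, height=subject.height,
        truth={
            "excitation": np.vstack([exc[n] for n in names]),
            "activation": np.vstack([act[n] for n in names]),
            "lm_norm": lm, "vm_norm": vm, "tendon_force": ft,
        },
    )
    if mode == "open_loop":
        return trial
    if mode != "minimal":
        raise ValueError(f"unknown mode {mode!r}")

    # replace truth by the minimal-effort solution on this trial
    from .redundancy import SolverOptions, solve_redundancy

    opts = solver_opts or SolverOptions(n_mesh=30)
    if (n_time - 1) % opts.n_mesh:
        raise ValueError("n_time - 1 must be a multiple of the solver mesh")
    sol = solve_redundancy(trial, subject.muscles, "GEN", opts=opts,
                           constants=constants)
    interp = lambda arr: np.vstack([np.interp(t, sol.time, row) for row in arr])
    trial.truth = {
        "excitation": interp(sol.excitation),
        "activation": interp(sol.activation),
        "lm_norm": interp(sol.lm_norm),
        "vm_norm": interp(sol.vm_norm),
        "tendon_force": interp(sol.tendon_force),
    }
    # moments regenerated from the solution's tendon forces: zero reserves
    trial.moments = np.einsum("mdk,mk->dk", arms, trial.truth["tendon_force"])
    return trial


def process_emg(raw, fs, band=(20.0, 400.0), lowpass=6.0, order=4):
    """EMG processing chain: zero-lag band-pass, full-wave rectification,
    zero-lag low-pass envelope.  ``fs`` must exceed twice the band's upper
    edge (> 800 Hz for the default band)."""
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} too low for band-pass {band}")
    # filtfilt doubles the order: design at half
    b, a = butter(order // 2, [band[0] / (fs / 2), band[1] / (fs / 2)], "bandpass")
    x = filtfilt(b, a, raw)
    x = np.abs(x)
    b, a = butter(order // 2, lowpass / (fs / 2), "lowpass")
    return filtfilt(b, a, x)


def make_emg_envelopes(trial: GaitTrial, channels, seed: int,
                       noise_sd: float = 0.01, gain_seed: int | None = None):
    """Attach noisy gain-scaled envelopes of the true excitations.

    Per-channel gains are drawn log-uniform in [0.3, 3] and returned so tests
    can verify the EMG-workflow scale-factor recovery; pipeline consumers
    should treat them as hidden.  ``gain_seed`` (default: ``seed``) controls
    the gain draw separately from the noise so that one subject's channels
    keep the same gains across trials.
    """
    rng = np.random.default_rng((seed, 2))
    grng = np.random.default_rng((seed if gain_seed is None else gain_seed, 4))
    gains = {}
    for ch in channels:
        i = trial.muscle_names.index(ch)
        g = float(np.exp(grng.uniform(np.log(0.3), np.log(3.0))))
        noise = rng.normal(0.0, noise_sd, trial.time.size)
        # smooth the noise like a 6 Hz envelope would be
        kernel = np.exp(-0.5 * (np.arange(-5, 6) / 2.0) ** 2)
        noise = np.convolve(noise, kernel / kernel.sum(), mode="same")
        trial.emg[ch] = np.clip(g * trial.truth["excitation"][i] + noise, 0.0, None)
        gains[ch] = g
    return gains


def make_gas_exchange(rate_w: float, duration: float = 360.0, seed: int = 0,
                      rer: float = 0.85, noise: float = 0.0,
                      breath_interval: float = 4.0,
                      brockway=(16.58, 4.51)) -> GasExchangeSeries:
    """Breath-by-breath VO2/VCO2 whose noiseless Brockway power equals
    ``rate_w`` exactly, at a fixed respiratory exchange ratio."""
    if rate_w <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng((seed, 3))
    n = int(duration / breath_interval)
    jitter = rng.uniform(0.85, 1.15, n) if noise > 0 else np.ones(n)
    times = np.cumsum(breath_interval * jitter)
    c_o2, c_co2 = brockway
    vo2 = rate_w / (c_o2 + c_co2 * rer)            # mL/s
    vco2 = rer * vo2
    mult = 1.0 + noise * rng.standard_normal(n) if noise > 0 else np.ones(n)
    mult = np.clip(mult, 0.2, None)
    return GasExchangeSeries(times=times, vo2=vo2 * 60.0 * mult,
                             vco2=vco2 * 60.0 * mult)
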