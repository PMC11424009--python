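"""Statistical comparisons for gait-cycle curves and scalar outcomes.

- repeated-measures correlation (common within-subject slope, ANCOVA with a
  subject factor);
- one-dimensional non-parametric mapping for paired time-series: pointwise
  paired t with a family-wise threshold from the sign-flip permutation
  distribution of the maximum statistic, plus cluster-extent p-values;
- Wilcoxon signed-rank (exact for small n, via scipy);
- curve agreement metrics (Pearson r, rmse) and excitation on/off timing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats as sps

__all__ = [
    "RmcorrResult",
    "Snpm1dResult",
    "rmcorr",
    "snpm_paired_1d",
    "wilcoxon_signed_rank",
    "agreement_metrics",
    "onoff_timing",
    "resample_cycle",
]


@dataclass
class RmcorrResult:
    slope: float
    r: float
    df: int
    p: float
    dropped_subjects: tuple = ()


@dataclass
class Snpm1dResult:
    t_curve: np.ndarray
    threshold: float
    clusters: list          # (start %, end %, cluster p)
    alpha: float
    n_permutations: int
    exhaustive: bool
    meta: dict = field(default_factory=dict)


def rmcorr(subjects, x, y) -> RmcorrResult:
    """Repeated-measures correlation.

    Fits a common slope after removing between-subject variance (ANCOVA with
    subject as factor); ``r`` carries the slope's sign, with
    df = N_obs - N_subjects - 1.  Subjects with fewer than 2 observations
    are dropped with a warning.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids, counts = np.unique(subjects, return_counts=True)
    dropped = tuple(ids[counts < 2].tolist())
    if dropped:
        warnings.warn(f"dropping subjects with a single observation: {dropped}")
        keep = ~np.isin(subjects, list(dropped))
        subjects, x, y = subjects[keep], x[keep], y[keep]
        ids = ids[counts >= 2]
    if ids.size < 2:
        raise ValueError("rmcorr needs >= 2 subjects with >= 2 observations")
    xc = x.copy()
    yc = y.copy()
    for s in ids:
        sel = subjects == s
        xc[sel] -= x[sel].mean()
        yc[sel] -= y[sel].mean()
    sxx = float(np.sum(xc * xc))
    syy = float(np.sum(yc * yc))
    sxy = float(np.sum(xc * yc))
    if sxx <= 0 or syy <= 0:
        raise ValueError("no within-subject variance")
    slope = sxy / sxx
    r = sxy / np.sqrt(sxx * syy)
    df = x.size - ids.size - 1
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return RmcorrResult(slope=slope, r=float(r), df=int(df), p=float(p),
                        dropped_subjects=dropped)


def _sign_matrix(n, max_exhaustive=4096, n_mc=10000, rng=None):
    if 2**n <= max_exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        return signs, True
    rng = rng or np.random.default_rng(0)
    signs = rng.choice([1.0, -1.0], size=(n_mc, n))
    return signs, False


def _paired_t(d):
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    return mean / np.maximum(sd, 1e-300) * np.sqrt(n)


def snpm_paired_1d(curves_a, curves_b, alpha: float = 0.05,
                   two_tailed: bool = True, n_permutations: int = 10000,
                   seed: int = 0) -> Snpm1dResult:
    """Non-parametric 1-D paired comparison of subject curve sets.

    ``curves_a``/``curves_b`` are (n_subjects, n_time) on a common cycle
    normalization.  The null distribution comes from sign flips of the
    subject difference curves: exhaustive when 2^n <= 4096, else seeded
    Monte-Carlo.  The family-wise threshold is the (1-alpha) quantile of the
    permutation maximum |t|; suprathreshold clusters get extent-based p.
    """
    A = np.atleast_2d(np.asarray(curves_a, dtype=float))
    B = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("curve sets must have matching shapes")
    n, nt = A.shape
    if n < 4:
        warnings.warn(f"only {n} subjects: the exact permutation set is tiny")
    d = A - B
    t_obs = _paired_t(d)
    stat = np.abs(t_obs) if two_tailed else t_obs

    signs, exhaustive = _sign_matrix(
        n, n_mc=n_permutations, rng=np.random.default_rng(seed))
    # permutation max-statistic distribution
    t_perm = np.einsum("pn,nt->pt", signs, d) / n
    sd_perm = np.sqrt(
        (np.einsum("nt,pn->pt", d**2, signs**2) - n * t_perm**2)
        / (n - 1))
    t_perm = t_perm / np.maximum(sd_perm, 1e-300) * np.sqrt(n)
    stat_perm = np.abs(t_perm) if two_tailed else t_perm
    maxdist = stat_perm.max(axis=1)
    P = maxdist.size
    idx = max(int(np.ceil((1.0 - alpha) * P)) - 1, 0)
    threshold = float(np.sort(maxdist)[idx])

    # suprathreshold clusters with extent p-values
    def cluster_extents(curve):
        above = curve > threshold
        out = []
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, nt - 1))
        return out

    perm_max_extent = np.array([
        max((b - a + 1 for a, b in cluster_extents(stat_perm[p_])), default=0)
        for p_ in range(P)
    ])
    clusters = []
    for a_, b_ in cluster_extents(stat):
        extent = b_ - a_ + 1
        p_clu = float(np.mean(perm_max_extent >= extent))
        clusters.append((100.0 * a_ / (nt - 1), 100.0 * b_ / (nt - 1),
                         max(p_clu, 1.0 / P)))
    return Snpm1dResult(t_curve=t_obs, threshold=threshold, clusters=clusters,
                        alpha=alpha, n_permutations=P, exhaustive=exhaustive)


def wilcoxon_signed_rank(x, y=None, two_tailed: bool = True):
    """Wilcoxon signed-rank test on paired samples (exact for n <= 12).

    Zero differences are dropped (Wilcoxon's original policy); ties among
    the remaining ranks use midranks.  Returns (p, statistic).
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero")
        return 1.0, 0.0
    if nz.size < 4:
        warnings.warn("fewer than 4 nonzero differences")
    method = "exact" if nz.size <= 12 else "auto"
    res = sps.wilcoxon(nz, alternative="two-sided" if two_tailed else "greater",
                       method=method, zero_method="wilcox")
    return float(res.pvalue), float(res.statistic)


def agreement_metrics(computed, reference):
    """(Pearson r, rmse) between a computed and a reference curve on a
    common grid.  r is nan (with a warning) for a constant reference."""
    c = np.asarray(computed, dtype=float)
    r = np.asarray(reference, dtype=float)
    if c.shape != r.shape:
        raise ValueError("curves must share the grid")
    rmse = float(np.sqrt(np.mean((c - r) ** 2)))
    if np.std(r) == 0 or np.std(c) == 0:
        warnings.warn("correlation undefined for a constant curve")
        return float("nan"), rmse
    return float(np.corrcoef(c, r)[0, 1]), rmse


def onoff_timing(excitation, threshold: float = 0.5):
    """On/off intervals (% cycle) where the self-normalized curve exceeds
    ``threshold``."""
    e = np.asarray(excitation, dtype=float)
    peak = e.max()
    if peak <= 0:
        return []
    norm = e / peak
    above = norm > threshold
    out = []
    start = None
    n = e.size
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((100.0 * start / (n - 1), 100.0 * (i - 1) / (n - 1)))
            start = None
    if start is not None:
        out.append((100.0 * start / (n - 1), 100.0))
    return out


def resample_cycle(time, values, n: int = 101):
    """Resample a cycle curve to ``n`` evenly spaced points (0-100%)."""
    t = np.asarray(time, dtype=float)
    tn = np.linspace(t[0], t[-1], n)
    return np.interp(tn, t, np.asarray(values, dtype=float))
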