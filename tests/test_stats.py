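"""Statistical operations against independent oracles."""
import warnings
from itertools import product

import numpy as np
import pytest

from gaitmet.stats import (
    agreement_metrics,
    onoff_timing,
    resample_cycle,
    rmcorr,
    snpm_paired_1d,
    wilcoxon_signed_rank,
)


class TestRmcorr:
    def test_parallel_lines_give_perfect_correlation(self):
        sub = np.array(["a"] * 5 + ["b"] * 5)
        x = np.concatenate([np.arange(5.0), np.arange(5.0) + 3])
        y = 2 * x + np.where(sub == "a", 1.0, -4.0)
        res = rmcorr(sub, x, y)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.df == 10 - 2 - 1

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "s": np.repeat(list("abcd"), 6),
            "x": rng.normal(size=24),
            "y": rng.normal(size=24),
        })
        mine = rmcorr(df.s.to_numpy(), df.x.to_numpy(), df.y.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_corr(df, x="x", y="y", subject="s")
        assert mine.r == pytest.approx(float(ref.r.iloc[0]), abs=1e-9)
        assert mine.p == pytest.approx(float(ref.pval.iloc[0]), abs=1e-9)
        assert mine.df == int(ref.dof.iloc[0])

    def test_matches_normal_equations_oracle(self):
        # ANCOVA normal equations: y ~ subject dummies + common slope
        rng = np.random.default_rng(5)
        sub = np.repeat(np.arange(3), 5)
        x = rng.normal(size=15)
        y = 0.7 * x + sub * 2.0 + rng.normal(size=15)
        X = np.column_stack([np.eye(3)[sub], x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert rmcorr(sub, x, y).slope == pytest.approx(beta[-1], abs=1e-10)

    def test_single_observation_subject_dropped_with_warning(self):
        sub = np.array(["a", "a", "a", "b", "b", "b", "c"])
        x = np.arange(7.0)
        y = 2 * x
        with pytest.warns(UserWarning, match="dropping"):
            res = rmcorr(sub, x, y)
        assert res.dropped_subjects == ("c",)

    def test_subject_reorder_invariance(self):
        rng = np.random.default_rng(11)
        sub = np.repeat(np.arange(4), 5)
        x, y = rng.normal(size=(2, 20))
        a = rmcorr(sub, x, y)
        perm = rng.permutation(20)
        b = rmcorr(sub[perm], x[perm], y[perm])
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 1000
        sub = np.repeat(np.arange(8), 5)
        for _ in range(reps):
            x, y = rng.normal(size=(2, 40))
            if rmcorr(sub, x, y).p < 0.05:
                hits += 1
        # binomial 95% interval around alpha=0.05 at 1000 reps
        assert 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / reps) <= hits / reps \
            <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps)


def _enumerate_threshold(d, alpha=0.05):
    """Independent exhaustive sign-flip max-|t| threshold."""
    n, nt = d.shape
    maxes = []
    for signs in product((1.0, -1.0), repeat=n):
        ds = np.asarray(signs)[:, None] * d
        t = ds.mean(0) / (ds.std(0, ddof=1) / np.sqrt(n))
        maxes.append(np.abs(t).max())
    maxes = np.sort(maxes)
    idx = int(np.ceil((1 - alpha) * len(maxes))) - 1
    return maxes[idx]


class TestSnpm1d:
    def test_identical_curves_give_no_clusters(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 101))
        res = snpm_paired_1d(A, A.copy())
        assert res.clusters == []

    def test_threshold_matches_exhaustive_enumeration_n5(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 101))
        B = rng.normal(size=(5, 101))
        res = snpm_paired_1d(A, B)
        assert res.exhaustive and res.n_permutations == 32
        assert res.threshold == pytest.approx(
            _enumerate_threshold(A - B), abs=1e-12)

    def test_constructed_effect_detected_as_one_cluster(self):
        rng = np.random.default_rng(7)
        A = rng.normal(0, 0.3, size=(8, 101))
        B = A + rng.normal(0, 0.3, size=(8, 101))
        B[:, 40:61] += 8.0                   # strong offset on 20% of cycle
        res = snpm_paired_1d(B, A)
        assert len(res.clusters) == 1
        start, end, p = res.clusters[0]
        assert start <= 41 and end >= 59
        assert p <= 0.05

    def test_subject_reorder_invariance(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 51))
        B = rng.normal(size=(6, 51))
        r1 = snpm_paired_1d(A, B)
        perm = rng.permutation(6)
        r2 = snpm_paired_1d(A[perm], B[perm])
        assert r1.threshold == pytest.approx(r2.threshold, abs=1e-12)

    def test_family_wise_error_near_alpha_under_null(self):
        rng = np.random.default_rng(77)
        reps, hits = 400, 0
        for _ in range(reps):
            d = rng.normal(size=(6, 31))
            res = snpm_paired_1d(d, np.zeros_like(d))
            if np.any(np.abs(res.t_curve) > res.threshold):
                hits += 1
        rate = hits / reps
        assert abs(rate - 0.05) <= 1.96 * np.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            snpm_paired_1d(np.zeros((5, 10)), np.zeros((5, 11)))


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        p, _ = wilcoxon_signed_rank(np.arange(1.0, 9.0), np.zeros(8))
        assert p == pytest.approx(2 / 2**8, abs=1e-12)

    def test_equal_samples_p_one(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning):
            p, _ = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_matches_full_enumeration_n6(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.4, 1.0, 6)
        p, _ = wilcoxon_signed_rank(d, np.zeros(6))
        # exhaustive null distribution of W+ over sign assignments
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        ws = np.array([np.asarray(s) @ ranks
                       for s in product((0.0, 1.0), repeat=6)])
        stat = min(w_obs, ranks.sum() - w_obs)
        p_exact = np.mean(np.minimum(ws, ranks.sum() - ws) <= stat)
        assert p == pytest.approx(p_exact, abs=1e-12)


class TestAgreementAndTiming:
    def test_identical_curves(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 50))
        assert agreement_metrics(x, x) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_constant_offset(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 50))
        r, rmse = agreement_metrics(x + 0.1, x)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(0.1)

    def test_five_point_hand_formula(self):
        c = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, rmse = agreement_metrics(c, ref)
        cc, rr = c - c.mean(), ref - ref.mean()
        assert r == pytest.approx(np.sum(cc * rr)
                                  / np.sqrt(np.sum(cc**2) * np.sum(rr**2)))
        assert rmse == pytest.approx(np.sqrt(2 / 5))

    def test_constant_reference_warns_nan(self):
        with pytest.warns(UserWarning):
            r, rmse = agreement_metrics(np.arange(5.0), np.ones(5))
        assert np.isnan(r)

    def test_rectangular_pulse_interval(self):
        i = np.arange(101)
        e = np.where((i >= 20) & (i <= 40), 1.0, 0.0)
        assert onoff_timing(e) == [(20.0, 40.0)]

    def test_threshold_above_max_gives_empty(self):
        assert onoff_timing(np.random.default_rng(0).random(50), 1.01) == []
        assert onoff_timing(np.zeros(50)) == []

    def test_two_pulses_in_order(self):
        i = np.arange(101)
        e = np.where((i >= 5) & (i <= 15), 1.0, 0.0) \
            + np.where((i >= 60) & (i <= 80), 0.9, 0.0)
        ivals = onoff_timing(e)
        assert len(ivals) == 2 and ivals[0][1] < ivals[1][0]

    def test_resample_cycle_endpoints(self):
        t = np.linspace(0, 1.1, 57)
        y = np.cos(t)
        out = resample_cycle(t, y, 101)
        assert out[0] == pytest.approx(y[0])
        assert out[-1] == pytest.approx(y[-1])
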