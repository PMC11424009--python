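"""Energy aggregation: Brockway conversion, whole-body averaging,
biarticular attribution, gait-phase shares, and anthropometric scaling."""
import numpy as np
import pytest

from gaitmet.aggregation import (
    GasExchangeSeries,
    brockway_rate,
    compute_max_isometric_force,
    muscle_group_rates,
    phase_relative_cost,
    representative_gas_value,
    split_biarticular,
    whole_body_average,
)
from gaitmet.trial import GaitEvents


class TestBrockway:
    def test_zero_input_zero_power(self):
        assert brockway_rate(0.0, 0.0) == 0.0

    def test_hand_arithmetic(self):
        # 16.58*5 + 4.51*4.1667
        assert brockway_rate(5.0, 4.1667) == pytest.approx(101.69, abs=0.01)

    def test_linearity(self):
        assert brockway_rate(6.0, 5.0) == pytest.approx(
            2 * brockway_rate(3.0, 2.5))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            brockway_rate(-1.0, 0.0)


class TestRepresentativeGasValue:
    def test_constant_series(self):
        t = np.arange(1, 91) * 4.0
        s = GasExchangeSeries(t, np.full(90, 300.0), np.full(90, 250.0))
        vo2, vco2 = representative_gas_value(s)
        assert vo2 == pytest.approx(5.0)
        assert vco2 == pytest.approx(250.0 / 60)

    def test_step_series_takes_last_window(self):
        t = np.arange(1, 91) * 4.0          # 6 min, 4-s breaths
        vo2 = np.where(t <= 180.0, 300.0, 400.0)
        s = GasExchangeSeries(t, vo2, vo2)
        v, _ = representative_gas_value(s)
        assert v == pytest.approx(400.0 / 60)

    def test_linear_ramp_mean(self):
        t = np.linspace(0.0, 360.0, 361)
        vo2 = 100.0 + t                      # mL/min ramp
        s = GasExchangeSeries(t[1:], vo2[1:], vo2[1:])
        v, _ = representative_gas_value(s)
        # closed-form mean of the ramp over (180, 360]; half a breath's
        # discretization slack
        assert v * 60 == pytest.approx(100.0 + 270.0, abs=0.6)

    def test_short_series_rejected(self):
        s = GasExchangeSeries([1.0, 50.0], [300.0, 300.0], [250.0, 250.0])
        with pytest.raises(ValueError):
            representative_gas_value(s)


class TestWholeBodyAverage:
    def test_zero_rates_return_basal_exactly(self):
        t = np.linspace(0, 1.1, 100)
        assert whole_body_average(np.zeros_like(t), t, 70.0, basal=1.2) == 1.2

    def test_constant_rate_arithmetic(self):
        t = np.linspace(0, 1.0, 200)
        m = 70.0
        edot = np.full_like(t, 1.5 * m)   # one-leg rate 1.5 W/kg, in W
        assert whole_body_average(edot, t, m, basal=1.2) == pytest.approx(4.2)

    def test_quadrature_matches_analytic_integral(self):
        t = np.linspace(0, 1.0, 1000)
        edot = 100.0 * (1 + np.sin(2 * np.pi * t)) / 2
        got = whole_body_average(edot, t, 70.0, basal=0.0)
        assert got == pytest.approx(2 * 50.0 / 70.0, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            whole_body_average(np.zeros(5), np.zeros(5), 70.0)


class TestBiarticularSplit:
    def test_moment_arm_ratio_example(self):
        # gastrocnemius-style: |r_ankle|=0.05, |r_knee|=0.02, Edot=10 W
        edot = np.full((1, 3), 10.0)
        arms = np.zeros((1, 2, 3))
        arms[0, 0] = -0.05                  # ankle
        arms[0, 1] = 0.02                   # knee
        att, flags = split_biarticular(
            edot, arms, ["gastroc"], ["ankle", "knee"],
            {"gastroc": ("ankle", "knee")})
        assert att[0, 0, 0] == pytest.approx(10 * 5 / 7)
        assert att[0, 1, 0] == pytest.approx(10 * 2 / 7)
        assert not flags

    def test_uniarticular_muscle_gets_everything(self):
        edot = np.full((1, 4), 3.0)
        arms = np.zeros((1, 2, 4))
        arms[0, 0] = -0.05
        att, _ = split_biarticular(edot, arms, ["soleus"], ["ankle", "knee"],
                                   {"soleus": ("ankle",)})
        np.testing.assert_allclose(att[0, 0], 3.0)
        np.testing.assert_allclose(att[0, 1], 0.0)

    def test_attribution_conserves_energy(self, gen_solution, subject):
        from gaitmet.metabolics import compute_metabolic_rates
        traj = compute_metabolic_rates("BH04", gen_solution, subject.muscles)
        spanned = {p.name: p.joints_spanned for p in subject.muscles}
        att, _ = split_biarticular(traj.edot, gen_solution.trial.arms,
                                   traj.muscle_names, gen_solution.trial.dofs,
                                   spanned)
        np.testing.assert_allclose(att.sum(axis=1), traj.edot, rtol=1e-12)

    def test_degenerate_arms_fall_back_to_cycle_average(self):
        edot = np.full((1, 3), 6.0)
        arms = np.zeros((1, 2, 3))
        arms[0, 0] = [0.04, 0.0, 0.04]
        arms[0, 1] = [0.02, 0.0, 0.02]
        att, flags = split_biarticular(edot, arms, ["m"], ["a", "b"],
                                       {"m": ("a", "b")})
        assert flags == {"m": 1}
        assert att[0, 0, 1] == pytest.approx(4.0)


class TestGroupRates:
    def test_single_muscle_group_and_permutation_invariance(self):
        t = np.linspace(0, 1, 50)
        edot = np.vstack([np.ones(50), 2 * np.ones(50)])
        arms = np.zeros((2, 1, 50))
        arms[:, 0] = 0.05
        spanned = {"m1": ("j",), "m2": ("j",)}
        att, _ = split_biarticular(edot, arms, ["m1", "m2"], ["j"], spanned)
        gmap = {("m1", "j"): "g1", ("m2", "j"): "g2"}
        series, shares = muscle_group_rates(att, t, ["m1", "m2"], ["j"], gmap)
        np.testing.assert_allclose(series["g1"], 1.0)
        assert sum(shares.values()) == pytest.approx(100.0)
        # reversed muscle order
        att2, _ = split_biarticular(edot[::-1], arms, ["m2", "m1"], ["j"],
                                    spanned)
        _, shares2 = muscle_group_rates(att2, t, ["m2", "m1"], ["j"], gmap)
        assert shares2 == pytest.approx(shares)

    def test_unmapped_muscle_rejected(self):
        att = np.ones((1, 1, 5))
        with pytest.raises(KeyError):
            muscle_group_rates(att, np.linspace(0, 1, 5), ["m"], ["j"], {})


class TestPhaseRelativeCost:
    def test_uniform_rate_splits_by_duration(self):
        t = np.linspace(0, 1, 1001)
        ev = GaitEvents(0.0, 0.6)
        st, sw = phase_relative_cost(np.ones_like(t), t, ev)
        assert st == pytest.approx(60.0, abs=1e-9)
        assert sw == pytest.approx(40.0, abs=1e-9)
        assert st + sw == pytest.approx(100.0, abs=1e-9)

    def test_swing_only_energy(self):
        t = np.linspace(0, 1, 1001)
        e = np.where(t > 0.6, 1.0, 0.0)
        st, sw = phase_relative_cost(e, t, GaitEvents(0.0, 0.6))
        assert sw == pytest.approx(100.0, abs=0.2)

    def test_piecewise_constant_hand_integration(self):
        # 2 W stance (60%), 1 W swing (40%) -> 75% / 25%
        t = np.linspace(0, 1, 100001)
        e = np.where(t <= 0.6, 2.0, 1.0)
        st, sw = phase_relative_cost(e, t, GaitEvents(0.0, 0.6))
        assert st == pytest.approx(75.0, abs=0.01)
        assert sw == pytest.approx(25.0, abs=0.01)

    def test_degenerate_phase_rejected(self):
        t = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            phase_relative_cost(np.ones_like(t), t, GaitEvents(0.0, 1.0))


class TestStrengthScaling:
    def test_regression_arithmetic(self):
        out = compute_max_isometric_force(
            71.3, 1.74, {"m": 1.0}, specific_tension=35.0, l_opt={"m": 0.1})
        v = 47.0 * 71.3 * 1.74 + 1285.0
        assert out["m"]["volume"] == pytest.approx(v)
        assert out["m"]["fmax"] == pytest.approx(35.0 * v / 10.0)
        assert out["m"]["mass"] == pytest.approx(v * 1e-6 * 1059.7)

    def test_specific_tension_proportionality(self):
        a = compute_max_isometric_force(70, 1.7, {"m": 1.0}, 35.0, {"m": 0.1})
        b = compute_max_isometric_force(70, 1.7, {"m": 1.0}, 70.0, {"m": 0.1})
        assert b["m"]["fmax"] == pytest.approx(2 * a["m"]["fmax"])

    def test_zero_fraction_zero_force(self):
        out = compute_max_isometric_force(
            70, 1.7, {"m": 1.0, "z": 0.0}, 35.0, {"m": 0.1, "z": 0.1})
        assert out["z"]["fmax"] == 0.0

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            compute_max_isometric_force(70, 1.7, {"m": 0.5}, 35.0, {"m": 0.1})
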