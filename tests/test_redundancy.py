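"""Muscle-redundancy solver: static closed forms, dynamic feasibility,
workflow relationships, and mesh-refinement stability."""
import numpy as np
import pytest
from scipy.optimize import minimize as sp_minimize

from gaitmet.redundancy import (
    SolverOptions,
    moment_balance_residual,
    solve_redundancy,
    static_optimize,
)
from gaitmet.synth import TENDON_GROUPS, make_emg_envelopes, make_gait_trial
from conftest import interp_rows


class TestStaticOptimize:
    def test_two_muscle_closed_form(self):
        # gains (40, 30) N*m, demand 10 N*m -> a = M G / sum(G^2)
        a, res = static_optimize(np.array([[40.0, 30.0]]), np.array([10.0]))
        np.testing.assert_allclose(a, [0.16, 0.12], atol=1e-6)
        assert abs(res[0]) < 1e-4

    def test_matches_qp_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            nm = rng.integers(2, 6)
            nd = rng.integers(1, 3)
            G = rng.uniform(5.0, 80.0, (nd, nm)) * rng.choice([-1, 1],
                                                              (nd, nm))
            tau = rng.uniform(-20.0, 20.0, nd)
            a, _ = static_optimize(G, tau)
            # independent oracle: SLSQP on the equality-constrained QP
            ref = sp_minimize(
                lambda x: np.sum(x**2), np.full(nm, 0.5),
                jac=lambda x: 2 * x, method="SLSQP",
                bounds=[(0.0, 1.0)] * nm,
                constraints={"type": "eq", "fun": lambda x: G @ x - tau,
                             "jac": lambda x: G},
                options={"ftol": 1e-14, "maxiter": 500})
            if ref.success:
                np.testing.assert_allclose(a, ref.x, atol=1e-5)


class TestSolveRedundancy:
    def test_zero_moments_need_no_activation(self, small_subject):
        tr = make_gait_trial(small_subject, 1.25, 3, n_time=151,
                             excitation_scale=0.0)
        sol = solve_redundancy(tr, small_subject.muscles, "GEN",
                               opts=SolverOptions(n_mesh=15))
        # residual passive/damping couplings leave milli-level activations
        assert np.max(sol.activation) < 0.01

    def test_recovers_minimal_effort_truth(self, subject, minimal_trial,
                                           gen_solution):
        a_true = interp_rows(gen_solution.time, minimal_trial.time,
                             minimal_trial.truth["activation"])
        rmse = np.sqrt(np.mean((gen_solution.activation - a_true) ** 2))
        assert rmse < 0.03

    def test_reserves_below_one_percent_of_peak(self, gen_solution):
        for dof, info in gen_solution.reserve_share().items():
            assert info["share"] < 0.01, dof

    def test_moment_balance_residual_small(self, gen_solution, minimal_trial):
        resid, maxabs = moment_balance_residual(gen_solution, minimal_trial)
        peak = np.max(np.abs(minimal_trial.moments), axis=1)
        assert np.all(maxabs < 1e-3 * np.maximum(peak, 1.0))

    def test_perturbed_activation_breaks_balance(self, gen_solution,
                                                 minimal_trial):
        import copy
        sol = copy.deepcopy(gen_solution)
        i = sol.muscle_names.index("soleus")
        sol.tendon_force[i] += 0.1 * np.max(sol.tendon_force[i])
        _, maxabs = moment_balance_residual(sol, minimal_trial)
        _, maxabs0 = moment_balance_residual(gen_solution, minimal_trial)
        j = gen_solution.dofs.index("ankle_dorsiflexion")
        assert maxabs[j] > maxabs0[j] * 10

    def test_unknown_workflow_rejected(self, minimal_trial, subject):
        with pytest.raises(ValueError):
            solve_redundancy(minimal_trial, subject.muscles, "XXX")

    def test_ten_requires_groups_and_emg_requires_map(self, minimal_trial,
                                                      subject):
        with pytest.raises(ValueError):
            solve_redundancy(minimal_trial, subject.muscles, "TEN")
        with pytest.raises(ValueError):
            solve_redundancy(minimal_trial, subject.muscles, "EMG")

    def test_mesh_refinement_stability(self, small_subject):
        tr = make_gait_trial(small_subject, 1.25, 3, n_time=301)
        sols = [solve_redundancy(tr, small_subject.muscles, "GEN",
                                 opts=SolverOptions(n_mesh=n))
                for n in (25, 50)]
        a_coarse = interp_rows(sols[1].time, sols[0].time, sols[0].activation)
        rmse = np.sqrt(np.mean((a_coarse - sols[1].activation) ** 2))
        assert rmse < 0.01


class TestWorkflows:
    def test_ten_objective_not_worse_than_frozen_generic(self, subject,
                                                         minimal_trial,
                                                         gen_solution):
        from gaitmet.redundancy import personalize_tendon_stiffness
        kt, sols = personalize_tendon_stiffness(
            [minimal_trial], subject.muscles, TENDON_GROUPS,
            opts=SolverOptions(n_mesh=30))
        assert sols[0].objective["total"] \
            <= gen_solution.objective["total"] + 1e-3
        for g, v in kt.items():
            assert 15.0 <= v <= 45.0

    def test_emg_workflow_respects_tracking_corridor(self, subject,
                                                     minimal_trial):
        import copy
        tr = copy.deepcopy(minimal_trial)
        channels = ["soleus", "vasti"]
        make_emg_envelopes(tr, channels, 21, noise_sd=0.0)
        sol = solve_redundancy(tr, subject.muscles, "EMG",
                               emg_map={c: c for c in channels},
                               tendon_groups=TENDON_GROUPS,
                               opts=SolverOptions(n_mesh=30))
        for ch in channels:
            i = sol.muscle_names.index(ch)
            env = np.interp(sol.time, tr.time, tr.emg[ch])
            dev = sol.excitation[i] - sol.emg_gains[ch] * env
            assert np.max(np.abs(dev)) <= 0.01 + 1e-6

    def test_missing_emg_channel_is_configuration_error(self, subject,
                                                        minimal_trial):
        with pytest.raises(KeyError):
            solve_redundancy(minimal_trial, subject.muscles, "EMG",
                             emg_map={"nonexistent": "soleus"},
                             opts=SolverOptions(n_mesh=10))
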