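"""Shared fixtures: one virtual subject and pre-solved gait cycles.

The heavier artifacts (a minimal-effort ground-truth trial and its
redundancy solution) are session-scoped so every test file can reuse them.
"""
import numpy as np
import pytest

from gaitmet.redundancy import SolverOptions, solve_redundancy
from gaitmet.synth import make_gait_trial, make_virtual_subject

SUBJECT_SEED = 1
TRIAL_SEED = 7


@pytest.fixture(scope="session")
def subject():
    return make_virtual_subject(SUBJECT_SEED)


@pytest.fixture(scope="session")
def trial(subject):
    """Open-loop ground-truth gait cycle at preferred speed."""
    return make_gait_trial(subject, 1.25, TRIAL_SEED, n_time=301)


@pytest.fixture(scope="session")
def minimal_trial(subject):
    """Trial whose ground truth is itself the minimal-effort solution."""
    return make_gait_trial(subject, 1.25, TRIAL_SEED, mode="minimal",
                           n_time=301)


@pytest.fixture(scope="session")
def gen_solution(subject, minimal_trial):
    """Minimal-effort redundancy solution of the minimal-effort trial."""
    return solve_redundancy(minimal_trial, subject.muscles, "GEN",
                            opts=SolverOptions(n_mesh=30))


@pytest.fixture(scope="session")
def small_subject():
    """Hip+knee-only subject (6 muscles) for fast solver experiments."""
    return make_virtual_subject(SUBJECT_SEED, n_muscles=6)


def interp_rows(t_new, t_old, arr):
    return np.vstack([np.interp(t_new, t_old, row) for row in arr])
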