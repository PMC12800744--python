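import warnings

import numpy as np
import pytest

import socialhgf as sh

warnings.filterwarnings("ignore", message="no restart converged")


@pytest.fixture(scope="session")
def default_schedule():
    return sh.make_schedule()


@pytest.fixture(scope="session")
def mr_params():
    return sh.ModelParams(variant="mean_reverting")


@pytest.fixture(scope="session")
def small_schedule():
    """Short task for EEG/GLM tests where full-length epochs are overkill."""
    return sh.make_schedule(sh.TaskConfig(
        n_trials=48, phase_lengths=(12, 24, 12), seed=9))


@pytest.fixture(scope="session")
def small_cohort_tables(small_schedule):
    """12 subjects' z-scored regressor tables on the short schedule."""
    rng = np.random.default_rng(2)
    tables = []
    for _ in range(12):
        p = sh.ModelParams(variant="mean_reverting",
                           omega2=-3 + 0.5 * rng.standard_normal(),
                           zeta=0.45, nu=2.0)
        traj = sh.filter_beliefs(p, small_schedule.u)
        table, _ = sh.regressor_table(traj, small_schedule, p.zeta)
        tables.append(table)
    return tables
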