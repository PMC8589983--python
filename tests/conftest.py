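"""Shared fixtures.

Fast fixtures use a coarser integration step (the model is stiff only on the
tau_r = 2 ms scale, so dt = 0.5 ms is still stable and accurate enough for
behavioral unit tests).  The full-resolution experiment tables are
session-scoped because several statistical tests share them.
"""

import numpy as np
import pytest

from adaptconf import (
    ExperimentPlan,
    ModelParameters,
    TrialProtocol,
    run_experiment,
)

FAST_DT = 5e-4


@pytest.fixture(scope="session")
def fast_params():
    return ModelParameters(dt=FAST_DT)


@pytest.fixture(scope="session")
def fast_protocol():
    return TrialProtocol()


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def default_protocol():
    return TrialProtocol()


@pytest.fixture(scope="session")
def adapt_table():
    """Default-scale experiment (10 sessions x 500 trials, adaptation)."""
    return run_experiment(ExperimentPlan(master_seed=101))


@pytest.fixture(scope="session")
def std_table():
    """Default-scale experiment under the short-term-depression variant."""
    return run_experiment(ExperimentPlan(master_seed=101, variant="std"))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
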