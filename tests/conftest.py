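import numpy as np
import pytest

from lipglm import synth
from lipglm.task import ShapeSet, TaskConfig, derive_stimulus_vars, sample_trial


@pytest.fixture(scope="session")
def shape_set():
    return ShapeSet()


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def shape_set_sw(shape_set):
    """Shape set whose subjective weights equal the assigned weights."""
    return shape_set.with_subjective(shape_set.weights)


@pytest.fixture(scope="session")
def small_trials(shape_set_sw, task_config):
    """50 chosen trials with derived variables, shared across fast tests."""
    rng = np.random.default_rng(11)
    trials = [sample_trial(shape_set_sw, task_config, rng, i) for i in range(50)]
    agent = synth.AgentSpec(shape_set_sw.subjective_weights)
    trials = synth.simulate_choices(trials, agent, rng)
    dvs = [derive_stimulus_vars(t, shape_set_sw) for t in trials]
    return trials, dvs


@pytest.fixture(scope="session")
def null_dataset():
    """A 200-trial session from one homogeneous (non-encoding) neuron."""
    return synth.generate_dataset(
        1, 200, cohort={"null": 1.0}, master_seed=21, variable_set="full"
    )
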