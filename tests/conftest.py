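import numpy as np
import pytest

import seqvalue as sv


@pytest.fixture(scope="session")
def walk():
    return sv.make_reward_walk(sv.TaskConfig(n_blocks=2, trials_per_block=40, seed=123))


@pytest.fixture(scope="session")
def tiny_cohort():
    return sv.make_fixture("tiny")


@pytest.fixture(scope="session")
def worked_example():
    return sv.make_fixture("worked_example")["trials"]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
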