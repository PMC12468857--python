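import numpy as np
import pytest

from softboil.dqn import QNetwork, QPolicy
from softboil.plant import NOMINAL_PARAMS, PlantParams
from softboil.profiles import build_serving_profile, build_training_profile


@pytest.fixture(scope="session")
def serving_profile():
    return build_serving_profile()


@pytest.fixture(scope="session")
def training_profile():
    return build_training_profile()


@pytest.fixture
def nominal_params() -> PlantParams:
    return NOMINAL_PARAMS


def make_threshold_policy() -> QPolicy:
    """A hand-crafted Q-network implementing a fixed threshold rule.

    Heat when the error (observation entry 2) is below -0.1 degC, cool when
    it is above +0.5 degC, otherwise idle.  The rule is wired directly into
    the network weights through three ReLU channels carrying e-, e+ shifted
    by the thresholds.  Useful as a deterministic, competent-but-untrained
    stand-in policy.
    """
    net = QNetwork(60, 4, (64, 64), np.random.default_rng(0))
    for p in net.parameters():
        p[...] = 0.0
    # hidden layer 1: channel 0 = relu(-e - 0.1), channel 1 = relu(e - 0.5)
    net.W[0][2, 0] = -1.0
    net.b[0][0] = -0.1
    net.W[0][2, 1] = 1.0
    net.b[0][1] = -0.5
    # hidden layer 2: pass-through
    net.W[1][0, 0] = 1.0
    net.W[1][1, 1] = 1.0
    # output: idle gets a small constant edge; heat/cool win past thresholds
    net.b[2][0] = 0.01
    net.W[2][0, 1] = 10.0
    net.W[2][1, 2] = 10.0
    net.b[2][3] = -100.0
    return QPolicy(net, meta={"kind": "threshold rule"})


@pytest.fixture(scope="session")
def threshold_policy() -> QPolicy:
    return make_threshold_policy()


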