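import numpy as np
import pytest
from hypothesis import settings

from muskel.synthetic import make_pendulum, make_planar_arm

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")
from muskel.system import State, build_system, default_state


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def double_pendulum_system():
    return build_system(make_pendulum(2, masses=[1.3, 0.7], lengths=[0.9, 0.7]))


@pytest.fixture(scope="session")
def arm_model():
    return make_planar_arm(2)


@pytest.fixture(scope="session")
def arm_system(arm_model):
    return build_system(arm_model)


def random_state(system, rng, q_scale=1.0, u_scale=1.0):
    nq = system.nq
    return State(0.0, q_scale * rng.normal(size=nq), u_scale * rng.normal(size=nq),
                 np.zeros(system.nz))
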