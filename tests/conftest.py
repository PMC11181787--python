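import numpy as np
import pytest

from ctdiscrim.imaging_chain import SYSTEM1, SYSTEM2, Condition
from ctdiscrim.observer_models import ObserverSpec, io_template


@pytest.fixture(scope="session")
def cond_t3_a1():
    return Condition.create("T3", SYSTEM1, "A1")


@pytest.fixture(scope="session")
def cond_t3_a2():
    return Condition.create("T3", SYSTEM1, "A2")


@pytest.fixture(scope="session")
def cond_t1_a1():
    return Condition.create("T1", SYSTEM2, "A1")


def make_io_observer(condition: Condition, theta: float, kappa: float = 0.0, label: str = "io"):
    mu_t, mu_a = condition.mean_images(theta)
    t = io_template(mu_t, mu_a, condition.noise, condition.apod, condition.display)
    return ObserverSpec(t, kappa, label)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
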