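import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dunbarlim as dl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_records():
    """Hand-enumerated 4-message forest: A replies twice to B, B once to A."""
    return [
        dl.MessageRecord("b1", "B"),
        dl.MessageRecord("a1", "A", "b1"),
        dl.MessageRecord("a2", "A", "b1"),
        dl.MessageRecord("b2", "B", "a1"),
    ]


@pytest.fixture
def toy_network(toy_records):
    return dl.project_to_network(dl.build_forest(toy_records))


@pytest.fixture(scope="session")
def small_substrate():
    return dl.make_substrate(150, gamma=-2.4, seed=9)


@pytest.fixture(scope="session")
def desk_result(small_substrate):
    """One instrumented desk-scale model run shared across tests."""
    cfg = dl.SimConfig(substrate=small_substrate, p=0.05, T=30, seed=4,
                       q_max=10)
    return dl.run_simulation(cfg, engine="traced", check_invariants=True)


def make_net(edges):
    net = dl.UserNetwork()
    for u, v, w in edges:
        net.add_reply(u, v, w)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
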