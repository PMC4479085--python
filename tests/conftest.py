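"""Shared fixtures: small analytic models and session-cached CME solves."""

import numpy as np
import pytest
from hypothesis import settings

import switchscape as sw
from switchscape.fixtures import make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny():
    """The small bistable switch fixture with its sparse stationary law."""
    fx = make_fixture("tiny_bistable")
    dist = sw.steady_state(fx.params, fx.grid, method="sparse")
    return fx, dist


@pytest.fixture(scope="session")
def slow_preset():
    return sw.preset("slow")


@pytest.fixture(scope="session")
def fast_preset():
    return sw.preset("fast")


@pytest.fixture(scope="session")
def fast_critical(fast_preset):
    return sw.find_critical_points(fast_preset)


@pytest.fixture(scope="session")
def fast_paths(fast_preset, fast_critical):
    """The two minimum-action switching paths of the fast regime."""
    net = sw.reduced_network(fast_preset)
    cp = fast_critical
    up = sw.gmam(cp.off, cp.on, net, n_images=100)
    dn = sw.gmam(cp.on, cp.off, net, n_images=100)
    return up, dn


@pytest.fixture(scope="session")
def slow_preset_dist(slow_preset):
    """Stationary CME solution at the slow reference parameters."""
    return sw.steady_state(slow_preset)
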