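import numpy as np
import pytest

from capnet.netgen import NetworkSpec, build_tree, rescale_asymmetry
from capnet.flow_solver import BoundaryConditions, solve
from capnet.pipeline import run_condition_pair


@pytest.fixture(scope="session")
def balanced_spec():
    """Perfectly symmetric tree: even splits, zero asymmetry, 16 terminals."""
    return NetworkSpec(root_diameter=40.0, terminal_diameter_target=14.0,
                       n_terminals_target=16, asymmetry_mean=0.0,
                       topology_skew=float("inf"), rng_seed=7)


@pytest.fixture(scope="session")
def balanced_tree(balanced_spec):
    return build_tree(balanced_spec)


@pytest.fixture(scope="session")
def small_spec():
    """Small but irregular network for fast structural tests."""
    return NetworkSpec(root_diameter=60.0, terminal_diameter_target=13.0,
                       n_terminals_target=48, rng_seed=11)


@pytest.fixture(scope="session")
def small_tree(small_spec):
    return build_tree(small_spec)


@pytest.fixture(scope="session")
def small_state(small_tree):
    return solve(small_tree, BoundaryConditions(12.0, 0.42))


@pytest.fixture(scope="session")
def study_pair():
    """The full default baseline / simulated-hyperinsulinemia pair.

    Built once per session: this is the network behind the headline model
    numbers and several tests interrogate different aspects of it.
    """
    return run_condition_pair()
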