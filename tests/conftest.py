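"""Shared fixtures: small binary networks and a reduced spiking network."""

import numpy as np
import pytest

from balanced_coding.binary import BinaryNetworkParams
from balanced_coding.spiking import (
    ArchitectureParams,
    StimulusProtocol,
    build_network,
)


@pytest.fixture
def small_params() -> BinaryNetworkParams:
    """6-neuron system (3 pools of 2): enumerable, moderate couplings."""
    return BinaryNetworkParams(
        n_pops=3, pop_size=2, beta=1.0, w_plus=0.2, w_inh=0.1,
        inputs=(0.3, 0.3, 0.3),
    )


@pytest.fixture
def weak_params() -> BinaryNetworkParams:
    """Weakly coupled system where mean field matches enumeration to ~1e-3."""
    return BinaryNetworkParams(
        n_pops=3, pop_size=4, beta=1.0, w_plus=0.006, w_inh=0.003,
        inputs=(0.2, 0.2, 0.2),
    )


@pytest.fixture
def decoupled_params() -> BinaryNetworkParams:
    return BinaryNetworkParams(
        n_pops=3, pop_size=5, beta=1.5, w_plus=0.0, w_inh=0.0,
        inputs=(0.4, -0.2, 0.0),
    )


@pytest.fixture
def low_cohesion_params() -> BinaryNetworkParams:
    """The low-cohesion regime used for the analytic sweeps."""
    return BinaryNetworkParams(
        n_pops=5, pop_size=100, beta=2.0, w_plus=0.5, w_inh=0.5,
        inputs=(1.0,) * 5,
    )


@pytest.fixture(scope="session")
def tiny_network():
    """Heavily reduced spiking network for fast plumbing tests."""
    arch = ArchitectureParams()
    return build_network(arch, scale=0.1)


@pytest.fixture(scope="session")
def short_protocol() -> StimulusProtocol:
    return StimulusProtocol(stabilization_ms=200.0, stimulus_ms=300.0)
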