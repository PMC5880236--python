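"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from cladevo.synthetic import CladeScenario, simulate_clade


@pytest.fixture(scope="session")
def default_clade():
    """The murid-like default scenario: 20 breaks on the (A,B)-ancestor
    branch, 19 on the outgroup branch, 6x-accelerated focal clade rates."""
    return simulate_clade(CladeScenario(seed=11))


@pytest.fixture(scope="session")
def jittered_clade():
    """Same scenario with 5% of block boundaries jittered."""
    return simulate_clade(CladeScenario(seed=11, boundary_jitter_fraction=0.05))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
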