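"""Shared fixtures: scenarios are simulated once per session and reused."""

import numpy as np
import pytest

from crossfeed.presets import scenario
from crossfeed.simulation import simulate_batch


@pytest.fixture(scope="session")
def wt_low_trajectory():
    return simulate_batch(scenario("wt"))


@pytest.fixture(scope="session")
def wt_high_trajectory():
    return simulate_batch(scenario("wt", buffer="conventional"))


@pytest.fixture(scope="session")
def aae_low_trajectory():
    return simulate_batch(scenario("aae"))


@pytest.fixture(scope="session")
def lae_low_trajectory():
    return simulate_batch(scenario("lae"))


@pytest.fixture(scope="session")
def wt_measured_trajectory():
    return simulate_batch(scenario("wt", family="measured"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
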