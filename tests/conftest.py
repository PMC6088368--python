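import numpy as np
import pytest
from hypothesis import settings

from reachrl import AgentParams, condition_preset, simulate_session

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

#: Agent with plausible human-scale variability used across tests.
STANDARD_AGENT = AgentParams(sigma_m=3.5, sigma_e_rewarded=1.5, sigma_e_unrewarded=3.0)


@pytest.fixture(scope="session")
def control_protocol():
    return condition_preset("control")


@pytest.fixture(scope="session")
def control_session(control_protocol):
    """One standard-schedule control session, shared read-only."""
    return simulate_session(control_protocol, STANDARD_AGENT, seed=42)


@pytest.fixture(scope="session")
def short_session():
    """A 100-trial session (40 baseline + 60 rotation) for filter tests."""
    from reachrl import Block, TaskProtocol

    protocol = TaskProtocol(
        blocks=(Block("BL1", 40, 0.0), Block("R1", 60, -15.0)),
        rotation_sign_order=-1,
    )
    return simulate_session(protocol, STANDARD_AGENT, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
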