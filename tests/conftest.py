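"""Shared fixtures.

Expensive end-to-end simulations are session-scoped so that several tests can
interrogate the same deterministic run; everything is generated in-process
from the shipped configuration.
"""

import numpy as np
import pytest
from hypothesis import settings

from colligaze.config import default_config
from colligaze.experiment import simulate_condition

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cond15(config):
    """Full pipeline for a 15 deg gaze shift, straight-ahead eye and head."""
    return simulate_condition(config, 15.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def cond40(config):
    """Full pipeline for a 40 deg gaze shift (head strongly recruited)."""
    return simulate_condition(config, 40.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230517)
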