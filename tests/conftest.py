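import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import coopbind as cb

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ident_rates():
    """Identical independent sites, K_o = 1 uM^-1, all coefficients 1."""
    return cb.RateConstants(1, 1, 1, 1, 1, 1, 1, 1)


@pytest.fixture(scope="session")
def coop10_rates():
    """Positive cooperativity preset: K_o = 1, omega = 10."""
    return cb.RateConstants.cooperative(1.0, 10.0)


@pytest.fixture(scope="session")
def hidden_rates():
    """Strong negative cooperativity: K_o = 1, omega = 0.02."""
    return cb.RateConstants.cooperative(1.0, 0.02)


@pytest.fixture(scope="session")
def coop10_isotherm(coop10_rates):
    """Simulated equilibrium isotherm of the omega = 10 scenario (coarse
    grid for speed; 5 points per decade over 0.01-100 uM)."""
    grid = cb.ligand_grid(1.0, per_decade=5)
    return cb.simulate_isotherm(coop10_rates, 1.0, grid)
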