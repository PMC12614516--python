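"""Shared fixtures: published-table curves/parameters and synthetic media."""

import numpy as np
import pytest

from swavekvfd import KVFDParams, load_fixture

# Weak-loss medium used for detector validation: loss angle stays below
# 4 degrees across 40-180 Hz, so group and phase arrival nearly coincide
# and knee picks can be compared against phase velocity.
WEAK_LOSS = KVFDParams(E0=5000.0, eta=15.0, alpha=0.5)

BAND = np.array([40.0, 60.0, 80.0, 100.0, 120.0, 140.0, 160.0, 180.0])


@pytest.fixture(scope="session")
def hard_curve():
    """Measured hard-phantom dispersion replicates (packaged table)."""
    return load_fixture("table2")


@pytest.fixture(scope="session")
def soft_curve():
    """Measured soft-phantom dispersion replicates (packaged table)."""
    return load_fixture("table3")


@pytest.fixture(scope="session")
def published_params():
    """KVFD parameter sets per (phantom, method) from the published fits."""
    return load_fixture("table4")


@pytest.fixture(scope="session")
def bias_table():
    """Published frequency-resolved loss-angle / inflation table."""
    return load_fixture("table5")


@pytest.fixture
def weak_loss_params():
    return WEAK_LOSS
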