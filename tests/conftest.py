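import logging

import numpy as np
import pytest

from floodring.growth_model import GrowthModelFit
from floodring.io_formats import RingSeries
from floodring.synthetic_data import SimConfig, simulate_study

logging.getLogger("floodring").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study at a fixed seed, shared across tests."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture
def growth_fit():
    return GrowthModelFit(beta0=60.0, beta1=20.0, beta2=2.0)


@pytest.fixture
def make_series():
    """Factory for quick RingSeries construction."""
    def _make(widths, first_year=2000, sid="S1", **kw):
        return RingSeries(series_id=sid, tree_id=sid, first_year=first_year,
                          widths=list(widths), **kw)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
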