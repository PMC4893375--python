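import numpy as np
import pytest

from mcti.tissue_model import (LayerProperties, TissueSample,
                               load_extinction_table, load_parameter_ranges)
from mcti.transport import SimulationConfig


@pytest.fixture(scope="session")
def table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def colon_ranges():
    return load_parameter_ranges("colon")


@pytest.fixture(scope="session")
def generic_ranges():
    return load_parameter_ranges("generic")


@pytest.fixture(scope="session")
def fast_config():
    """Small photon count for unit tests; variance is tracked explicitly."""
    return SimulationConfig(n_photons=5_000, seed=42, weight_threshold=1e-2)


@pytest.fixture
def single_layer_sample():
    layer = LayerProperties(v_hb=0.05, s=0.6, a_mie=18.9, b=1.286, g=0.85,
                            n_refr=1.36, d=1500.0)
    return TissueSample((layer,))


@pytest.fixture
def colon_sample(colon_ranges):
    from mcti.tissue_model import sample_tissue
    return sample_tissue(colon_ranges, 1, seed=3)[0]
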