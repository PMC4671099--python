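import numpy as np
import pytest

import poctherm as pt


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def simple_model():
    """Single-segment age model: 100 m/Ma, surface node included."""
    return pt.AgeModel.from_nodes("SIMPLE", [0.0, 100.0], [0.0, 1.0])


@pytest.fixture
def kinked_model():
    """Two-segment model: 50 m/Ma above 50 m, 200 m/Ma below."""
    return pt.AgeModel.from_nodes("KINK", [0.0, 50.0, 100.0], [0.0, 1.0, 1.25])


@pytest.fixture
def default_params():
    return pt.ArrheniusParams()


@pytest.fixture
def flat_geotherm():
    """Zero gradient: constant temperature at all depths."""
    def make(temp_c: float) -> pt.GeothermFit:
        return pt.GeothermFit("FLAT", temp_c, 0.0, 1.0, 3)
    return make


@pytest.fixture(scope="session")
def small_ensemble():
    """Shared 40-site synthetic ensemble with the default (effect) kinetics."""
    return pt.generate_dataset(pt.SynthConfig(n_sites=40, seed=424242))
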