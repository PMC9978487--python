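import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, max_examples=50)
settings.load_profile("default")

from bacclim.model_core import EnvForcing, ModelParams, partition_biomass
from bacclim.scenario_synth import build_grid


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def oxic_forcing():
    """Forcing with a finite, converging steady state (low DOC, POC-driven)."""
    return EnvForcing(T=15.0, DOC=1.0, POC=10.0, DO=250.0, Z=0.5, P=1.0, z=25.0)


@pytest.fixture
def small_grid():
    return build_grid(18, 36)


@pytest.fixture
def state_factory():
    def make(B=1.0, DOC=10.0, POC=5.0):
        return partition_biomass(B, DOC, POC)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
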