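import numpy as np
import pytest

from natps.model import CoupledHarmonicModel, ModelParams
from natps.tps import default_basins


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def model(params) -> CoupledHarmonicModel:
    return CoupledHarmonicModel(params)


@pytest.fixture(scope="session")
def basins():
    return default_basins()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
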