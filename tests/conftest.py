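import numpy as np
import pytest

from mfsnn import (
    DriftSpec,
    LIFParams,
    MFSNN,
    ModelConfig,
    PopulationSpec,
    make_population,
    simulate_session,
)


@pytest.fixture(scope="session")
def desk_spec() -> PopulationSpec:
    """64-channel, 8-direction center-out population at default signal levels."""
    return PopulationSpec(n_channels=64, paradigm="center_out_8")


@pytest.fixture(scope="session")
def desk_session(desk_spec):
    pop = make_population(desk_spec, seed=7)
    return simulate_session(pop, 300, seed=11)


@pytest.fixture()
def tiny_config() -> ModelConfig:
    """A small but complete architecture: 16 channels, 2 sub-encoders."""
    return ModelConfig.build(n_channels=16, n_subencoders=2, n_classes=4, seed=0)


@pytest.fixture()
def tiny_model(tiny_config) -> MFSNN:
    return MFSNN(tiny_config)


@pytest.fixture()
def tiny_batch() -> np.ndarray:
    rng = np.random.default_rng(42)
    return rng.poisson(1.0, size=(6, 16, 20)).astype(float)
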