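import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shellmech import CantileverSpec, GeneratorConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cantilever() -> CantileverSpec:
    """Bruker-style probe: 350 pN/nm, 20 nm tip."""
    return CantileverSpec(k_cantilever=350.0, R_tip=20.0)


@pytest.fixture
def quiet_cfg() -> GeneratorConfig:
    """Noiseless generator configuration."""
    return GeneratorConfig(seed=0, noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
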