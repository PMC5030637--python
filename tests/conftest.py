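import numpy as np
import pytest

from phytopattern import ModelParams


@pytest.fixture
def reference_params() -> ModelParams:
    """The reference parameter set used throughout the study figures."""
    return ModelParams(eta=0.1, kappa=0.6, delta=0.02, gamma_nl=0.5, alpha_nl=0.125)


@pytest.fixture
def bistable_params() -> ModelParams:
    """Aridity inside the bistable range (vegetated branches exist)."""
    return ModelParams(eta=0.08, kappa=0.6, delta=0.02, gamma_nl=0.5, alpha_nl=0.125)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
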