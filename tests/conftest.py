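import numpy as np
import pytest

from protmut.model_core import ModelParams


@pytest.fixture
def worked_params() -> ModelParams:
    """Standard net-protective parameter set used throughout the examples."""
    return ModelParams(
        r=1.0, q=0.4, b=1.0, gamma=0.1, alpha=0.5,
        delta_E=0.1, delta_M=0.1, u=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140918)
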