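import numpy as np
import pytest

from kalmantd import ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Simulation defaults: σw²=1, σr²=1, τ²=0.01, α=0.3, γ=0.98, 4 bins."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150917)
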