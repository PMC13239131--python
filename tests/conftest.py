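import numpy as np
import pytest

from floodsim import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neutral_params():
    """All selection switched off: every multiplier and penalty neutral."""
    return ModelParams(
        survival_mult_L2L2=1.0,
        repro_mult_L2L2=1.0,
        fecundity_mult_one_homo=1.0,
        fecundity_mult_both_homo=1.0,
        mating_penalty=0.0,
    )


@pytest.fixture
def tiny_params():
    """Small, fast parameterization for structural tests."""
    return ModelParams(K=60, generations=5, seed=7)
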