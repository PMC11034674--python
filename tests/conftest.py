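import numpy as np
import pytest

from adaptlab import ModelParams, tsay_like_truth


@pytest.fixture(scope="session")
def truth():
    """The planted correction-function ground truth."""
    return tsay_like_truth()


@pytest.fixture(scope="session")
def moe_params():
    """Memory-of-errors engine with the literature parameter estimates."""
    return ModelParams(engine="moe", a=0.945, b0=0.037, alpha=0.9568, beta=0.0558)


@pytest.fixture(scope="session")
def nlmc_params():
    return ModelParams(engine="nlmc", a=0.945, sim_scale=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
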