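import numpy as np
import pytest

from exogait.synthetic_gait import GaitSimConfig, simulate_session


@pytest.fixture(scope="session")
def noiseless_cfg() -> GaitSimConfig:
    return GaitSimConfig(n_strides=10, seed=1).noiseless()


@pytest.fixture(scope="session")
def noiseless_run(noiseless_cfg):
    """One shared noiseless simulated session with its ground truth."""
    return simulate_session(noiseless_cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
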