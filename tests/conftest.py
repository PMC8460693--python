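import dataclasses

import numpy as np
import pytest

from perfseg3d.experiment import default_small_config, prepare_case
from perfseg3d.phantom import PhantomConfig, generate_case


@pytest.fixture(scope="session")
def phantom_cfg() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def positive_case(phantom_cfg):
    return generate_case(dataclasses.replace(phantom_cfg, seed=101), positive=True)


@pytest.fixture(scope="session")
def negative_case(phantom_cfg):
    return generate_case(dataclasses.replace(phantom_cfg, seed=202), positive=False)


@pytest.fixture(scope="session")
def prepared_positive(positive_case):
    return prepare_case(positive_case, target_mm=2.0)


@pytest.fixture(scope="session")
def small_unet_config():
    return default_small_config().unet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
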