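import numpy as np
import pytest

from gapsim.amplify import GapsConfig
from gapsim.simulate import default_template, demo_genome


@pytest.fixture(scope="session")
def template():
    return default_template(seed=11)


@pytest.fixture(scope="session")
def config(template):
    return GapsConfig.from_template(template)


@pytest.fixture(scope="session")
def demo():
    return demo_genome(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
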