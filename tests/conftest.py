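import numpy as np
import pytest

from hwforecast import (GeneratorConfig, make_ghana_fixture, synth_norms)


@pytest.fixture(scope="session")
def ghana():
    """Published single-region 2016 baseline census and transition table."""
    return make_ghana_fixture()


@pytest.fixture(scope="session")
def ghana_census(ghana):
    return ghana[0]


@pytest.fixture(scope="session")
def ghana_tp(ghana):
    return ghana[1]


@pytest.fixture(scope="session")
def gen_cfg():
    """Default generator configuration (study-shaped conditions, fixed seed)."""
    return GeneratorConfig(seed=12345)


@pytest.fixture(scope="session")
def norms(gen_cfg):
    return synth_norms(gen_cfg)
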