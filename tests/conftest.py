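import numpy as np
import pytest

from tethersample import (
    ModelConfig,
    hairpin_wire_fixture,
    standin_nick_histogram,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def nick_hist():
    return standin_nick_histogram()


@pytest.fixture
def wn_config(nick_hist):
    return ModelConfig.from_name("WN", nick_histogram=nick_hist)


@pytest.fixture
def uu_config():
    return ModelConfig.from_name("UU")


def model_config(name):
    """Model config for any of the four variants (stand-in nick histogram)."""
    hist = standin_nick_histogram() if name in ("UN", "WN") else None
    return ModelConfig.from_name(name, nick_histogram=hist)


@pytest.fixture
def h0_spec():
    return hairpin_wire_fixture("H0")


@pytest.fixture
def h1_spec():
    return hairpin_wire_fixture("H1")
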