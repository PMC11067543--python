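import numpy as np
import pytest

from statmirror import load_fixture
from statmirror.mirroring import named_preset


@pytest.fixture(scope="session")
def sample6():
    """Six-value random sample of the manual worked example."""
    return load_fixture("table2_sample")


@pytest.fixture(scope="session")
def scores4():
    """Four-score group used for the set-duplication study."""
    return load_fixture("table6_group1")


@pytest.fixture(scope="session")
def temperatures():
    """Monthly mean temperature series (deg C)."""
    return load_fixture("table4_temperatures").values


@pytest.fixture(scope="session")
def amm():
    return named_preset("absolute_meanic")


@pytest.fixture(scope="session")
def rmm():
    return named_preset("raw_meanic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240416)
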