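import numpy as np
import pytest

from pairscan import build_lookup_table, enumerate_patterns


@pytest.fixture(scope="session")
def patterns():
    return enumerate_patterns()


@pytest.fixture(scope="session")
def lookup_table(patterns):
    return build_lookup_table(patterns)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
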