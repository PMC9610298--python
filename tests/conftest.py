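import numpy as np
import pytest

from chesar import datasets


@pytest.fixture(scope="session")
def ki_table():
    return datasets.load_ki_table()


@pytest.fixture(scope="session")
def physchem_table():
    return datasets.load_physchem_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
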