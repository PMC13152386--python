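import numpy as np
import pytest

from replichar.synthetic_data import embleya_preset, generate_genome


@pytest.fixture(scope="session")
def embleya_dataset():
    """One generated Embleya-like genome shared across the suite."""
    return generate_genome(embleya_preset(), seed=1)


@pytest.fixture(scope="session")
def embleya_genome(embleya_dataset):
    return embleya_dataset.genome


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
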