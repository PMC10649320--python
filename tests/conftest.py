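import numpy as np
import pytest

from pirlstm import SyntheticSpec, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 50-pair synthetic benchmark shared by read-only tests."""
    return generate_benchmark(SyntheticSpec(n_per_class=50, seed=11))
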