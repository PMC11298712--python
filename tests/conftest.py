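import hypothesis
import numpy as np
import pytest

from presqkit import load_blosum30, synthetic_supplement

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=60
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def blosum30():
    return load_blosum30()


@pytest.fixture(scope="session")
def supplement():
    """One synthetic stand-in supplement (113 mito + 97 chloro TPs, 31 helices)."""
    return synthetic_supplement(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240723)
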