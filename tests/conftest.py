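import numpy as np
import pytest

from strucdiv import IndelWeightModel, load_substitution_matrix


@pytest.fixture(scope="session")
def blosum45():
    return load_substitution_matrix("BLOSUM45")


@pytest.fixture(scope="session")
def weight_model():
    """The (-2, 2, 4) saturating curve used throughout the examples."""
    return IndelWeightModel(c1=-2.0, c2=2.0, c3=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
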