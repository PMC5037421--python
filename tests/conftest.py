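import numpy as np
import pytest
from hypothesis import settings

from lcsalign.gap_model import GapModel
from lcsalign.substitution import load_matrix

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def miqs():
    return load_matrix("MIQS")


@pytest.fixture(scope="session")
def model():
    return GapModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length):
    return "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=length))
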