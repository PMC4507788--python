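import numpy as np
import pytest

from swathpep.fixtures import MockPredictor, default_models

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mock_predictor():
    return MockPredictor(default_models(("A02", "A03", "B07")))


def random_peptide(rng, length=None, min_len=8, max_len=12):
    if length is None:
        length = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
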