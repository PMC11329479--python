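import numpy as np
import pytest

from gpse.core import MuellerMatrix, normalize_mueller
from gpse.synth import random_physical_mueller


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_mueller_batch(rng):
    """Factory for batches of normalized random physical Mueller matrices."""

    def make(n: int):
        return [normalize_mueller(random_physical_mueller(rng)) for _ in range(n)]

    return make


@pytest.fixture
def identity():
    return MuellerMatrix.identity()
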