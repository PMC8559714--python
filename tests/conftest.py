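import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from strobeseed.simulate import random_sequence  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_dna():
    """Factory for reproducible random DNA strings."""

    def make(length: int, seed: int = 0) -> str:
        return random_sequence(length, seed)

    return make
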