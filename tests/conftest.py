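import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from segfuse import ProbabilityMapSet


@pytest.fixture
def random_maps():
    """Factory: seeded uniform-random probability map sets."""

    def make(seed: int, shape=(64, 64), class_ids=(1, 2, 3)) -> ProbabilityMapSet:
        rng = np.random.default_rng(seed)
        return ProbabilityMapSet(
            rng.uniform(0.0, 1.0, (len(class_ids), *shape)), class_ids
        )

    return make


@pytest.fixture
def random_label_arrays():
    """Factory: pairs of seeded random label arrays over {0,1,2,3}."""

    def make(seed: int, shape=(24, 24), p_fg=0.6):
        rng = np.random.default_rng(seed)
        def one():
            arr = rng.integers(1, 4, shape)
            arr[rng.uniform(size=shape) > p_fg] = 0
            return arr
        return one(), one()

    return make
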