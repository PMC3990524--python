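import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_nonconstant(rng, n):
    """A random binary vector guaranteed nonconstant."""
    while True:
        v = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        if 0 < v.sum() < n:
            return v


@pytest.fixture
def small_dataset():
    """A tiny planted dataset: 2 identity, 2 negation, 1 XOR pair, 40 background."""
    from logicmine import SyntheticConfig, generate

    cfg = SyntheticConfig(
        n_per_phenotype=(16, 16),
        n_background=40,
        lower_plants={1: 2, 2: 2},
        lower_noise=0.0,
        higher_plants={"XOR": 1},
        higher_noise=0.0,
        seed=11,
    )
    return generate(cfg)


@pytest.fixture
def toy_matrix():
    m = pd.DataFrame(
        [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 1, 1], [1, 1, 1, 1]],
        index=["f1", "f2", "f3", "f4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    p = pd.DataFrame(
        [[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"], columns=["s1", "s2", "s3", "s4"]
    )
    return m, p
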