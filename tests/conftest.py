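import numpy as np
import pytest

from rankfuse.fusion import ProbabilityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture
def random_matrices(rng):
    """1,000 random two-class probability matrices with K in 1..5."""
    matrices = []
    for _ in range(1000):
        k = int(rng.integers(1, 6))
        p_fake = rng.random(k)
        matrices.append(ProbabilityMatrix(np.column_stack([1 - p_fake, p_fake])))
    return matrices
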