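import numpy as np
import pytest

from scdropgan.io import ExpressionMatrix, preprocess
from scdropgan.simulate import preset, simulate


@pytest.fixture(scope="session")
def small_truth():
    """A small sim71-regime dataset with known dropout mask and labels."""
    return simulate(preset("sim71", seed=11, n_cells=300, n_genes=150))


@pytest.fixture(scope="session")
def small_preprocessed(small_truth):
    return preprocess(small_truth.observed)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_matrix():
    values = np.array([[0.0, 5.0, 1.0],
                       [2.0, 0.0, 3.0],
                       [4.0, 6.0, 0.0],
                       [1.0, 1.0, 1.0]])
    return ExpressionMatrix(values, [f"c{i}" for i in range(4)],
                            [f"g{j}" for j in range(3)])
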