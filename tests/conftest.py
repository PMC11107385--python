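import numpy as np
import pytest

from atmm.core import CountMatrix


@pytest.fixture
def nb_matrix():
    """Factory for seeded negative-binomial count matrices."""

    def make(seed: int, n_genes: int = 200, n_samples: int = 4,
             size: float = 5.0, p: float = 0.05) -> CountMatrix:
        rng = np.random.default_rng(seed)
        counts = rng.negative_binomial(size, p, size=(n_genes, n_samples))
        return CountMatrix(
            counts,
            [f"gene_{i}" for i in range(n_genes)],
            [f"sample_{j}" for j in range(n_samples)],
        )

    return make


@pytest.fixture
def tiny_cm():
    return CountMatrix([[1, 2], [3, 4]], ["g1", "g2"], ["s1", "s2"])


@pytest.fixture
def identical_cm():
    col = np.array([5, 80, 13, 200, 41, 7, 66, 120, 9, 33])
    counts = np.column_stack([col, col, col])
    return CountMatrix(counts, [f"g{i}" for i in range(10)], ["a", "b", "c"])
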