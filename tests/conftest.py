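import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from neurostage.connectivity import BinaryAdjacency, WeightedAdjacency


def binary_from_matrix(a: np.ndarray) -> BinaryAdjacency:
    a = np.asarray(a)
    n = a.shape[0]
    density = a.sum() / (n * (n - 1))
    return BinaryAdjacency(
        matrix=a.astype(np.int8),
        density=float(density),
        source_threshold=0.0,
        node_labels=[str(i) for i in range(n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_k4():
    """Two disjoint 4-cliques; the canonical Q = 0.5 example."""
    a = np.zeros((8, 8), dtype=int)
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    a[i, j] = 1
    return a


@pytest.fixture
def star5():
    """Star: center node 0 with 4 leaves."""
    a = np.zeros((5, 5), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    return a


@pytest.fixture
def cycle5():
    a = np.zeros((5, 5), dtype=int)
    for i in range(5):
        a[i, (i + 1) % 5] = a[(i + 1) % 5, i] = 1
    return a


def weighted_from_edges(n: int, edges: dict[tuple[int, int], float]) -> WeightedAdjacency:
    m = np.zeros((n, n))
    for (i, j), w in edges.items():
        m[i, j] = m[j, i] = w
    return WeightedAdjacency(matrix=m, node_labels=[str(i) for i in range(n)])
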