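import numpy as np
import pytest

from connvalid import RegionSet, WeightedConnectome


def random_region_set(n: int, rng: np.random.Generator, box: float = 20.0) -> RegionSet:
    return RegionSet(
        labels=tuple(f"A{k}" for k in range(n)),
        centroids=rng.uniform(0, box, size=(n, 3)),
    )


def random_count_matrix(
    n: int, rng: np.random.Generator, symmetric: bool = False, high: int = 100
) -> np.ndarray:
    W = rng.integers(0, high, size=(n, n)).astype(float)
    np.fill_diagonal(W, 0.0)
    if symmetric:
        W = np.triu(W, k=1)
        W = W + W.T
    return W


def make_counts(
    n: int, rng: np.random.Generator, symmetric: bool = False, high: int = 100
) -> WeightedConnectome:
    regions = random_region_set(n, rng)
    return WeightedConnectome(
        regions=regions,
        W=random_count_matrix(n, rng, symmetric=symmetric, high=high),
        directed=not symmetric,
        kind="count",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
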