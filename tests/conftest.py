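import numpy as np
import pytest

from fuzzylump import (
    MarkovChain,
    build_chain,
    karate_fixture,
    load_network,
    network_from_adjacency,
)


@pytest.fixture(scope="session")
def triangle():
    return load_network("1 2\n2 3\n1 3", format="edgelist", weighted=False)


@pytest.fixture(scope="session")
def triangle_chain(triangle):
    return build_chain(triangle)


@pytest.fixture(scope="session")
def karate_chain():
    return build_chain(karate_fixture())


@pytest.fixture
def random_chain_factory():
    """Factory for random connected weighted chains of a given size."""

    def make(n: int, seed: int) -> MarkovChain:
        rng = np.random.default_rng(seed)
        W = rng.random((n, n))
        W = np.triu(W, 1)
        W = W + W.T
        # keep it connected and strictly positive off-diagonal
        return build_chain(network_from_adjacency(W))

    return make


@pytest.fixture
def random_membership_factory():
    def make(n: int, k: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.dirichlet(np.ones(k), size=n)

    return make
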