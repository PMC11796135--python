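import numpy as np
import pytest

from netkda import GeneNetwork, GeneSignature
from netkda import synthetic


@pytest.fixture
def chain_net() -> GeneNetwork:
    return GeneNetwork(edges=[("a", "b"), ("b", "c"), ("c", "d")], name="chain")


@pytest.fixture
def star_net() -> GeneNetwork:
    """Hub regulating 10 leaves, plus two disconnected spare nodes."""
    edges = [("hub", f"leaf{i}") for i in range(10)]
    return GeneNetwork(edges=edges, nodes=["spare1", "spare2"], name="star")


def random_network(seed: int, n: int = 200, p: float = 0.02) -> GeneNetwork:
    """Sparse random directed graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = [(f"g{i}", f"g{j}") for i, j in zip(*np.nonzero(mask))]
    return GeneNetwork(edges=edges, nodes=[f"g{i}" for i in range(n)],
                       name=f"random-{seed}")


@pytest.fixture(scope="session")
def planted_bundle():
    """One default-scale synthetic dataset shared by slower tests."""
    net, truth = synthetic.generate_network(seed=7)
    sig_a, sig_b = synthetic.generate_signatures(truth)
    return net, truth, sig_a, sig_b
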