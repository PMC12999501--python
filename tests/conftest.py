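import numpy as np
import pytest

from ddnetmap import GeneNetwork, PlantedNetworkSpec, gen_network


@pytest.fixture
def two_node():
    return GeneNetwork([("a", "b", 1.0)])


@pytest.fixture
def path3():
    return GeneNetwork([("a", "b", 1.0), ("b", "c", 1.0)])


@pytest.fixture
def star4():
    return GeneNetwork([("h", "x", 1.0), ("h", "y", 1.0), ("h", "z", 1.0)])


@pytest.fixture
def two_triangles():
    edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
    return GeneNetwork(edges)


@pytest.fixture(scope="session")
def planted_sbm():
    """The standard 4-community planted benchmark (n=200)."""
    return gen_network(PlantedNetworkSpec(
        n_genes=200, n_communities=4, p_within=0.15, p_between=0.01,
        rng_seed=42))


def random_network(rng: np.random.Generator, n_max: int = 30) -> GeneNetwork:
    """A small random weighted network with at least one edge."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        p = float(rng.uniform(0.15, 0.5))
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(iu.size) < p
        if keep.sum() == 0:
            continue
        w = rng.uniform(0.1, 2.0, size=int(keep.sum()))
        edges = [(f"n{i}", f"n{j}", float(x))
                 for i, j, x in zip(iu[keep], ju[keep], w)]
        return GeneNetwork(edges)
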