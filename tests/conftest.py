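import numpy as np
import pytest
from hypothesis import settings

from anubix import GeneSet, GeneSetCollection, Network, SynthSpec, generate_network

settings.register_profile("repro", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture
def path_network() -> Network:
    """The path graph a–b–c–d."""
    return Network([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def gs():
    def make(*genes, id="S", name=""):
        return GeneSet(id=id, name=name or id, members=frozenset(genes))

    return make


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted-module network shared across tests (read-only)."""
    spec = SynthSpec(
        n_genes=600,
        modules=tuple((60, 0.3) for _ in range(3)),
        p_out=0.01,
        seed=7,
    )
    network, pathways, manifest = generate_network(spec)
    return network, pathways, manifest


def random_graph(rng: np.random.Generator, n_nodes: int, p: float = 0.3) -> Network:
    """Seeded Erdős–Rényi test graph with string node names."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return Network(edges, genes=names)
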