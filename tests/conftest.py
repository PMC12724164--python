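import networkx as nx
import numpy as np
import pytest

from dendromorph import GeneratorConfig, NeuronTree, generate_population


def build_tree(edges, positions, root=0):
    """NeuronTree from an edge list and a node->xyz mapping."""
    g = nx.DiGraph()
    for v, p in positions.items():
        g.add_node(v, pos=np.asarray(p, dtype=float))
    g.add_edges_from(edges)
    return NeuronTree(g, root)


@pytest.fixture
def cherry():
    """Root with two unit-length leaf children."""
    return build_tree(
        [(0, 1), (0, 2)],
        {0: (0, 0, 0), 1: (1, 0, 0), 2: (0, 1, 0)},
    )


@pytest.fixture
def caterpillar3():
    """3-leaf caterpillar with unit reduced edges (W = 4)."""
    return build_tree(
        [(0, 1), (0, 2), (2, 3), (2, 4)],
        {0: (0, 0, 0), 1: (0, 0, 1), 2: (1, 0, 0), 3: (1, 1, 0), 4: (2, 0, 0)},
    )


@pytest.fixture
def tuft_tree():
    """Soma -> long neurite (w=10) -> node a -> two branches -> four leaves.

    Phi(a) = 1 - 6/16 + 4/4 = 1.625; Phi(b) = Phi(c) = 1.375.
    """
    return build_tree(
        [("r", "a"), ("a", "b"), ("a", "c"),
         ("b", "b1"), ("b", "b2"), ("c", "c1"), ("c", "c2")],
        {
            "r": (0, 0, 0),
            "a": (10, 0, 0),
            "b": (10, 1, 0),
            "c": (10, -1, 0),
            "b1": (11, 1, 0),
            "b2": (10, 1, 1),
            "c1": (11, -1, 0),
            "c2": (10, -1, -1),
        },
        root="r",
    )


def random_neuron_tree(n=50, seed=0):
    """Random rooted tree with random 3-D positions (random recursive tree)."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_node(0, pos=rng.normal(size=3) * 10)
    for v in range(1, n):
        parent = int(rng.integers(0, v))
        g.add_node(v, pos=rng.normal(size=3) * 10)
        g.add_edge(parent, v)
    return NeuronTree(g, 0)


@pytest.fixture(scope="session")
def small_population():
    """One shared synthetic population for the integration-level tests."""
    return generate_population(GeneratorConfig(seed=11, n_columns=10))


@pytest.fixture(scope="session")
def small_population_labels(small_population):
    return small_population.labels.set_index("neuron_id")
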