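import itertools

import networkx as nx
import numpy as np
import pytest

from netloc import PPINetwork, AnnotationTable, VOCABULARY


@pytest.fixture
def triangle():
    return PPINetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def path_abc():
    return PPINetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star():
    return PPINetwork.from_edges([("H", f"L{i}") for i in range(4)])


@pytest.fixture
def k4():
    nodes = ["A", "B", "C", "D"]
    return PPINetwork.from_edges(list(itertools.combinations(nodes, 2)))


def random_network(seed: int, n_max: int = 40) -> PPINetwork:
    """Erdős–Rényi graph with random size and density, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.05, 0.6))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    return PPINetwork.from_edges([(f"P{u}", f"P{v}") for u, v in g.edges()],
                                 vertices=[f"P{u}" for u in g.nodes()])


def brute_force_triangles(net: PPINetwork, u: str, v: str) -> int:
    """Independent oracle: count vertex triples forming a triangle on edge u–v."""
    count = 0
    for w in net.vertices:
        if w in (u, v):
            continue
        if (tuple(sorted((u, w))) in net.edges
                and tuple(sorted((v, w))) in net.edges):
            count += 1
    return count


def random_tables(seed: int, n_proteins: int = 30,
                  ) -> tuple[AnnotationTable, AnnotationTable]:
    """Random (pred, truth) table pair; truth sets always nonempty."""
    rng = np.random.default_rng(seed)
    terms = list(VOCABULARY)
    pred = AnnotationTable("PRED")
    truth = AnnotationTable("SCL")
    for i in range(n_proteins):
        p = f"P{i}"
        t_size = int(rng.integers(1, 4))
        truth[p] = set(rng.choice(terms, size=t_size, replace=False))
        p_size = int(rng.integers(0, 4))
        if p_size:
            pred[p] = set(rng.choice(terms, size=p_size, replace=False))
    return pred, truth
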