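import itertools

import networkx as nx
import numpy as np
import pytest

from riccinet import ProbabilityMeasure, WeightedNetwork


@pytest.fixture
def triangle() -> WeightedNetwork:
    return WeightedNetwork([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])


@pytest.fixture
def path5() -> WeightedNetwork:
    return WeightedNetwork([(i, i + 1, 1.0) for i in range(4)])


@pytest.fixture
def weighted_star() -> WeightedNetwork:
    """Star center 'c' with leaf weights 1 and 3 (walk measure 1/4, 3/4)."""
    return WeightedNetwork([("c", "l1", 1.0), ("c", "l2", 3.0)])


def complete_net(n: int) -> WeightedNetwork:
    return WeightedNetwork(
        [(i, j, 1.0) for i, j in itertools.combinations(range(n), 2)]
    )


def cycle_net(n: int) -> WeightedNetwork:
    return WeightedNetwork([(i, (i + 1) % n, 1.0) for i in range(n)])


def star_net(n_leaves: int) -> WeightedNetwork:
    return WeightedNetwork([("hub", f"leaf{i}", 1.0) for i in range(n_leaves)])


def random_connected_net(rng: np.random.Generator, max_nodes: int = 15) -> WeightedNetwork:
    """Random connected graph with random positive weights."""
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.25, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    comps = list(nx.connected_components(g))
    for a, b in zip(comps, comps[1:]):  # stitch components together
        g.add_edge(min(a), min(b))
    edges = [(u, v, float(rng.uniform(0.2, 2.0))) for u, v in g.edges]
    return WeightedNetwork(edges, nodes=range(n))


def random_measure(
    rng: np.random.Generator, points: list[str], max_support: int | None = None
) -> ProbabilityMeasure:
    hi = len(points) if max_support is None else min(max_support, len(points))
    k = int(rng.integers(1, hi + 1))
    support = sorted(rng.choice(points, size=k, replace=False).tolist())
    mass = rng.dirichlet(np.ones(k))
    mass = mass / mass.sum()
    return ProbabilityMeasure(tuple(support), tuple(float(m) for m in mass))
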