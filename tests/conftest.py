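import itertools

import pytest

from corepeel import Graph


def clique_edges(labels):
    return list(itertools.combinations(labels, 2))


@pytest.fixture
def k4():
    return Graph(clique_edges(["a", "b", "c", "d"]))


@pytest.fixture
def k4_pendant():
    """K4 on a-d plus pendant node e attached to clique node a."""
    return Graph(clique_edges(["a", "b", "c", "d"]) + [("a", "e")])


@pytest.fixture
def two_k6():
    left = [f"l{i}" for i in range(6)]
    right = [f"r{i}" for i in range(6)]
    return Graph(clique_edges(left) + clique_edges(right))


def naive_core_numbers(g: Graph) -> list[int]:
    """Definitional core-number oracle: for increasing k, repeatedly delete
    any node of residual degree < k; nodes removed during round k have core
    number k - 1 ... equivalently, a node's core number is the largest k for
    which it survives the pruning."""
    core = [0] * g.n
    alive = set(range(g.n))
    k = 0
    while alive:
        k += 1
        while True:
            doomed = [
                v for v in alive if len(g.adj[v] & alive) < k
            ]
            if not doomed:
                break
            for v in doomed:
                core[v] = k - 1
                alive.discard(v)
    return core
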