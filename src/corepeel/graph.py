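"""Graph container and density / core-decomposition primitives.

A protein–protein interaction network (PPIN) is modelled as a simple
undirected graph: no self-loops, no parallel edges, no edge weights.
External protein identifiers (arbitrary strings) are mapped to dense
integer indices at construction time; every algorithm in this package
operates on indices and maps back to labels only at output boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Graph",
    "CoreInfo",
    "average_degree",
    "density",
    "is_gamma_quasi_clique",
    "core_decomposition",
    "core_counts",
]


class Graph:
    """Simple undirected graph with string node labels and integer indices.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v)`` label pairs.  Self-loops and duplicate /
        reciprocal pairs are silently collapsed.
    nodes:
        Optional iterable of labels to include even when isolated.  Label
        order of first appearance (``nodes`` first, then ``edges``) fixes
        the integer indexing, which in turn fixes every deterministic
        tie-break downstream.
    """

    __slots__ = ("node_labels", "_index", "adj", "n", "m")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        self.node_labels: list[str] = []
        self._index: dict[str, int] = {}
        self.adj: list[set[int]] = []
        self.m = 0
        for label in nodes:
            self._intern(label)
        for u_lab, v_lab in edges:
            u = self._intern(u_lab)
            v = self._intern(v_lab)
            self.add_edge_idx(u, v)
        self.n = len(self.node_labels)

    def _intern(self, label: str) -> int:
        idx = self._index.get(label)
        if idx is None:
            idx = len(self.node_labels)
            self._index[label] = idx
            self.node_labels.append(label)
            self.adj.append(set())
            self.n = idx + 1
        return idx

    def add_edge_idx(self, u: int, v: int) -> None:
        """Add an undirected edge between existing indices (no-op for loops/dups)."""
        if u == v or v in self.adj[u]:
            return
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.m += 1

    def index_of(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def neighbors(self, v: int) -> set[int]:
        return self.adj[v]

    def edges_idx(self) -> Iterable[tuple[int, int]]:
        for u in range(self.n):
            for v in self.adj[u]:
                if u < v:
                    yield (u, v)

    def labels(self, idx_set: Iterable[int]) -> frozenset[str]:
        return frozenset(self.node_labels[i] for i in idx_set)

    def indices(self, labels: Iterable[str]) -> set[int]:
        """Indices of the given labels, skipping labels absent from the graph."""
        return {self._index[x] for x in labels if x in self._index}

    def induced_edge_count(self, Q: Iterable[int]) -> int:
        q = set(Q)
        return sum(len(self.adj[v] & q) for v in q) // 2

    def copy(self) -> "Graph":
        g = Graph(nodes=self.node_labels)
        for u, v in self.edges_idx():
            g.add_edge_idx(u, v)
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class CoreInfo:
    """Per-node core numbers C(v) and core counts CC(v).

    The core number C(v) is the largest k such that v belongs to a subgraph
    in which every node has degree >= k.  The core count CC(v) is the number
    of neighbours of v whose core number is at least C(v); among nodes of
    equal core number it discriminates the locally best-connected ones.
    """

    core: tuple[int, ...]
    core_count: tuple[int, ...]


def average_degree(g: Graph) -> float:
    """Average degree 2m/n of the whole graph."""
    if g.n == 0:
        raise ValueError("empty graph")
    return 2.0 * g.m / g.n


def density(g: Graph, Q: Iterable[int]) -> float:
    """Density of the subgraph induced by ``Q``: |E_Q| / C(|Q|, 2).

    Defined only for |Q| >= 2; callers treat smaller sets as automatic
    failures rather than special-casing the zero denominator here.
    """
    q = set(Q)
    k = len(q)
    if k < 2:
        raise ValueError("undefined density")
    return g.induced_edge_count(q) / (k * (k - 1) / 2)


def is_gamma_quasi_clique(g: Graph, Q: Iterable[int], gamma: float) -> bool:
    """True iff every node of G[Q] has induced degree >= gamma * (|Q| - 1).

    The comparison is exact (>=, no tolerance): induced degrees are integers
    and the bound is a plain product.
    """
    q = set(Q)
    bound = gamma * (len(q) - 1)
    return all(len(g.adj[v] & q) >= bound for v in q)


def core_decomposition(g: Graph) -> list[int]:
    """Core number of every node, by bucketed minimum-degree removal.

    Bucket-queue formulation running in O(n + m): nodes are kept sorted by
    current degree in an array of buckets; repeatedly the minimum-degree
    node is removed and its neighbours' degrees (and bucket positions)
    are decremented.
    """
    n = g.n
    if n == 0:
        return []
    deg = [len(g.adj[v]) for v in range(n)]
    max_deg = max(deg)
    # bin[d] = start position of degree-d block in vert
    bin_start = [0] * (max_deg + 1)
    for d in deg:
        bin_start[d] += 1
    start = 0
    for d in range(max_deg + 1):
        count = bin_start[d]
        bin_start[d] = start
        start += count
    pos = [0] * n
    vert = [0] * n
    next_free = bin_start.copy()
    for v in range(n):
        pos[v] = next_free[deg[v]]
        vert[pos[v]] = v
        next_free[deg[v]] += 1
    core = deg.copy()
    for i in range(n):
        v = vert[i]
        for u in g.adj[v]:
            if core[u] > core[v]:
                # swap u with the first node of its degree block, then shrink it
                du = core[u]
                pu = pos[u]
                pw = bin_start[du]
                w = vert[pw]
                if u != w:
                    vert[pu], vert[pw] = w, u
                    pos[u], pos[w] = pw, pu
                bin_start[du] += 1
                core[u] -= 1
    return core


def core_counts(g: Graph, core: Sequence[int]) -> list[int]:
    """CC(v) = number of neighbours of v with core number >= C(v)."""
    return [
        sum(1 for u in g.adj[v] if core[u] >= core[v]) for v in range(g.n)
    ]


def compute_core_info(g: Graph) -> CoreInfo:
    core = core_decomposition(g)
    return CoreInfo(core=tuple(core), core_count=tuple(core_counts(g, core)))


def ego_coverage(g: Graph, Q: Iterable[int]) -> float:
    """Largest fraction of the other members adjacent to a single member.

    A value of 1.0 means some member (a "center") is adjacent to every other
    member, i.e. the set lies in that member's closed 1-neighbourhood.
    """
    q = set(Q)
    if len(q) < 2:
        return 1.0
    return max(len(g.adj[v] & q) / (len(q) - 1) for v in q)
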