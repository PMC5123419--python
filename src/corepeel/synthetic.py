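"""Synthetic benchmarks: planted quasi-cliques, random baselines, noise.

Real PPINs embed their complexes as dense, largely ego-centric subgraphs.
The generator here emulates that structure directly: a sparse Erdős–Rényi
background plus planted complexes, each densified until it is a
``gamma_plant``-quasi-clique (every member adjacent to at least
gamma_plant * (size - 1) of the others), with optional pairwise member
overlaps.  The ground truth is returned alongside the graph, so recovery
can be scored exactly.

Three random baselines calibrate the quality measures: Rand1 redraws the
gold-standard size distribution from all graph vertices, Rand2 from only
the vertices covered by some gold complex, and Rand3 applies one global
vertex permutation to the gold standard (preserving all intersection
sizes).  Noise-edge injection supports robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import ceil
from typing import Mapping, Sequence

import numpy as np

from .evaluation import ClusterSet
from .graph import Graph

__all__ = [
    "SyntheticTruth",
    "generate_planted",
    "rand1",
    "rand2",
    "rand3",
    "add_noise_edges",
]


@dataclass
class SyntheticTruth:
    """A generated graph with its planted complexes and generation record."""

    graph: Graph
    truth: ClusterSet
    params: dict = field(default_factory=dict)


def _label(i: int) -> str:
    return f"p{i:04d}"


def _allocate_members(
    n: int,
    sizes: Sequence[int],
    overlap_pairs: Mapping[tuple[int, int], int],
    rng: np.random.Generator,
) -> list[set[int]]:
    """Assign node indices to complexes honouring pairwise overlap sizes."""
    members: list[set[int]] = [set() for _ in sizes]
    pool = list(rng.permutation(n))
    for (i, j), k in sorted(overlap_pairs.items()):
        if i == j or not (0 <= i < len(sizes)) or not (0 <= j < len(sizes)):
            raise ValueError(f"invalid overlap pair ({i}, {j})")
        if len(members[i]) + k > sizes[i] or len(members[j]) + k > sizes[j]:
            raise ValueError("infeasible overlap specification")
        if len(pool) < k:
            raise ValueError("not enough nodes for requested overlaps")
        shared = [pool.pop() for _ in range(k)]
        members[i].update(shared)
        members[j].update(shared)
    for idx, size in enumerate(sizes):
        need = size - len(members[idx])
        if need < 0 or len(pool) < need:
            raise ValueError("not enough nodes to realise complex sizes")
        members[idx].update(pool.pop() for _ in range(need))
    return members


def generate_planted(
    n: int = 200,
    p_bg: float = 0.05,
    sizes: Sequence[int] = (10, 10, 10, 10, 10),
    gamma_plant: float = 1.0,
    overlap_pairs: Mapping[tuple[int, int], int] | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Erdős–Rényi background with planted gamma-quasi-cliques.

    Each planted complex receives uniformly random missing member-pair
    edges until every member has within-complex degree at least
    ceil(gamma_plant * (size - 1)); with ``gamma_plant=1`` the complex is a
    clique.  Deterministic given ``seed``.
    """
    if any(s < 3 for s in sizes):
        raise ValueError("complex sizes must be >= 3")
    if not (0.5 < gamma_plant <= 1.0):
        raise ValueError("gamma_plant must be in (0.5, 1]")
    overlap_pairs = dict(overlap_pairs or {})
    rng = np.random.default_rng(seed)

    members = _allocate_members(n, sizes, overlap_pairs, rng)

    edges: set[tuple[int, int]] = set()
    if p_bg > 0:
        iu, iv = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < p_bg
        edges.update(zip(iu[mask].tolist(), iv[mask].tolist()))

    for group in members:
        size = len(group)
        target = ceil(gamma_plant * (size - 1))
        nodes = sorted(group)
        deg = {
            v: sum(
                1
                for u in nodes
                if u != v and (min(u, v), max(u, v)) in edges
            )
            for v in nodes
        }
        missing = [
            (a, b) for a, b in combinations(nodes, 2) if (a, b) not in edges
        ]
        order = rng.permutation(len(missing))
        for pos in order:
            if all(d >= target for d in deg.values()):
                break
            a, b = missing[pos]
            edges.add((a, b))
            deg[a] += 1
            deg[b] += 1
        if not all(d >= target for d in deg.values()):  # pragma: no cover
            raise RuntimeError("failed to densify planted complex")

    g = Graph(
        edges=((_label(a), _label(b)) for a, b in sorted(edges)),
        nodes=(_label(i) for i in range(n)),
    )
    truth = ClusterSet(
        [frozenset(_label(i) for i in group) for group in members],
        label="planted",
    )
    return SyntheticTruth(
        graph=g,
        truth=truth,
        params={
            "n": n,
            "p_bg": p_bg,
            "sizes": list(sizes),
            "gamma_plant": gamma_plant,
            "overlap_pairs": {f"{i},{j}": k for (i, j), k in overlap_pairs.items()},
            "seed": seed,
        },
    )


def _sample_sets(
    sizes: Sequence[int], universe: Sequence[str], rng: np.random.Generator
) -> list[frozenset[str]]:
    uni = np.asarray(sorted(universe), dtype=object)
    out = []
    for size in sizes:
        if size > uni.size:
            raise ValueError("universe smaller than requested set size")
        out.append(frozenset(rng.choice(uni, size=size, replace=False).tolist()))
    return out


def rand1(B: ClusterSet, V: Sequence[str], seed: int = 0) -> ClusterSet:
    """Random sets with B's size distribution, drawn from all vertices V."""
    rng = np.random.default_rng(seed)
    return ClusterSet(_sample_sets([len(b) for b in B], V, rng), label="rand1")


def rand2(B: ClusterSet, V: Sequence[str], seed: int = 0) -> ClusterSet:
    """As rand1, but drawing only from vertices covered by some gold complex."""
    covered = set().union(*B.sets) & set(V)
    rng = np.random.default_rng(seed)
    return ClusterSet(
        _sample_sets([len(b) for b in B], sorted(covered), rng), label="rand2"
    )


def rand3(B: ClusterSet, V: Sequence[str], seed: int = 0) -> ClusterSet:
    """One global vertex permutation applied to every gold complex.

    Preserves the size distribution and all pairwise intersection sizes.
    Labels outside V are left unchanged.
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(V)
    permuted = [ordered[i] for i in rng.permutation(len(ordered))]
    pi = dict(zip(ordered, permuted))
    return ClusterSet(
        [frozenset(pi.get(x, x) for x in b) for b in B], label="rand3"
    )


def add_noise_edges(g: Graph, fraction: float, seed: int = 0) -> Graph:
    """Add round(fraction * m) uniformly random new edges (original kept).

    New edges are drawn uniformly among the non-adjacent node pairs; the
    original adjacency is preserved as a subset.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    count = round(fraction * g.m)
    max_edges = g.n * (g.n - 1) // 2
    if g.m + count > max_edges:
        raise ValueError("not enough non-edges to add")
    rng = np.random.default_rng(seed)
    noisy = g.copy()
    added = 0
    while added < count:
        u = int(rng.integers(g.n))
        v = int(rng.integers(g.n))
        if u == v or v in noisy.adj[u]:
            continue
        noisy.add_edge_idx(u, v)
        added += 1
    return noisy
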