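"""The Core&Peel algorithm: approximate partial dense covers of a PPIN.

The algorithm looks for protein complexes as dense subgraphs lying inside
the closed 1-neighbourhood (ego-network) of some seed protein — a partial
dense cover PDC(G, r=1, delta, q): for each vertex v, the (approximately)
largest set of size >= q and density >= delta contained in v's ego-network
and containing v.  Exact computation is NP-complete; the four-phase
heuristic implemented here is:

  I.   core decomposition; sort vertices by (C(v), CC(v)) descending;
  II.  per seed v, form the candidate set {v} + neighbours with core
       number >= C(v); cheap count-based filters discard hopeless seeds;
  III. peel the candidate set — iteratively remove a minimum-degree node —
       until density >= delta (success) or size < q (failure);
  IV.  prune duplicates, subsets, and near-duplicate pairs by Jaccard
       similarity.

Everything is deterministic: all tie-breaks fall back to ascending node
index, fixed by label order in the input graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import CoreInfo, Graph, compute_core_info

__all__ = ["CorePeelParams", "Cluster", "core_and_peel"]


@dataclass(frozen=True)
class CorePeelParams:
    """User parameters of the partial dense cover PDC(G, r=1, delta, q).

    Attributes
    ----------
    q:
        Minimum cluster size (>= 2).
    delta:
        Target density in (0, 1] that a peeled cluster must reach.
    delta_low:
        Phase-II density rejection threshold; the default 1/2 is the
        Turán bound guaranteeing a large clique-like subgraph in any
        graph denser than half-complete.
    policy:
        Phase-II filter policy: 0 = density > delta_low; 1 = at least q
        nodes of induced degree >= (q - 1) * delta; 2 = pass if either.
    jaccard_max:
        Phase-IV pairwise Jaccard threshold: of two clusters more similar
        than this, one is dropped.
    r:
        Seed neighbourhood radius; fixed to 1 (ego-networks).
    """

    q: int = 4
    delta: float = 0.9
    delta_low: float = 0.5
    policy: int = 2
    jaccard_max: float = 0.8
    r: int = 1

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must be in (0, 1]")
        if not (0.0 <= self.delta_low <= 1.0):
            raise ValueError("delta_low must be in [0, 1]")
        if self.policy not in (0, 1, 2):
            raise ValueError("policy must be 0, 1 or 2")
        if not (0.0 < self.jaccard_max <= 1.0):
            raise ValueError("jaccard_max must be in (0, 1]")
        if self.r != 1:
            raise ValueError("only r=1 (ego-networks) is supported")


@dataclass(frozen=True)
class Cluster:
    """A predicted complex: a dense node set inside its seed's ego-network."""

    members: frozenset[int]
    seed: int
    density: float


def order_vertices(g: Graph, info: CoreInfo) -> list[int]:
    """Vertices sorted by (C(v), CC(v)) descending, index ascending on ties.

    Seeds of the largest, densest quasi-cliques come first: C(v) upper-bounds
    the size of the densest quasi-clique through v, and among equal cores the
    core count CC(v) favours the locally best-connected node (the would-be
    complex "leader" adjacent to all other members).
    """
    return sorted(range(g.n), key=lambda v: (-info.core[v], -info.core_count[v], v))


def candidate_set(g: Graph, info: CoreInfo, v: int) -> set[int]:
    """Seed v plus its neighbours of core number >= C(v)."""
    cv = info.core[v]
    s = {u for u in g.adj[v] if info.core[u] >= cv}
    s.add(v)
    return s


def _induced_degrees(g: Graph, s: set[int]) -> dict[int, int]:
    return {v: len(g.adj[v] & s) for v in s}


def passes_filter(g: Graph, s: set[int], params: CorePeelParams) -> bool:
    """Phase-II count-based filters deciding whether a seed is worth peeling.

    The size test |S| < q always applies.  Policy 0 requires the induced
    density to exceed ``delta_low`` (strict: density <= delta_low rejects);
    policy 1 requires at least q nodes of induced degree >= (q - 1) * delta,
    a necessary condition for a delta-quasi-clique of size q; policy 2
    passes if either does.
    """
    if len(s) < params.q:
        return False
    deg = _induced_degrees(g, s)
    k = len(s)
    if params.policy in (0, 2):
        dens = sum(deg.values()) / (k * (k - 1))
        if dens > params.delta_low:
            return True
        if params.policy == 0:
            return False
    bound = (params.q - 1) * params.delta
    return sum(1 for d in deg.values() if d >= bound) >= params.q


def peel(
    g: Graph,
    s: set[int],
    params: CorePeelParams,
    seed: int | None = None,
) -> Cluster | None:
    """Phase III: strip minimum-degree nodes until the residual set is dense.

    Before every removal the stopping rules are checked: success as soon as
    the induced density reaches ``delta`` (so an already-dense candidate is
    returned whole), failure as soon as fewer than ``q`` nodes remain.
    Among minimum-degree nodes the one minimising the neighbour-degree sum
    S(v) = sum_{w in N(v)} |N(w)| (on the residual subgraph) is removed;
    remaining ties go to the smallest node index.

    A success that no longer contains ``seed`` is discarded (returns None):
    the cover requires the seed to belong to its own set.
    """
    current = set(s)
    deg = _induced_degrees(g, current)
    m_cur = sum(deg.values()) // 2
    while True:
        k = len(current)
        if k < params.q:
            return None
        if m_cur / (k * (k - 1) / 2) >= params.delta:
            if seed is not None and seed not in current:
                return None
            anchor = seed if seed is not None else min(current)
            return Cluster(
                members=frozenset(current),
                seed=anchor,
                density=m_cur / (k * (k - 1) / 2),
            )
        min_deg = min(deg.values())
        best = None
        best_key = None
        for v in current:
            if deg[v] != min_deg:
                continue
            s_v = sum(deg[w] for w in g.adj[v] & current)
            key = (s_v, v)
            if best_key is None or key < best_key:
                best, best_key = v, key
        current.remove(best)
        for w in g.adj[best] & current:
            deg[w] -= 1
        m_cur -= min_deg
        del deg[best]


def _pairwise_intersections(
    member_sets: list[frozenset[int]], alive: list[bool]
) -> dict[tuple[int, int], int]:
    """Intersection sizes of all overlapping alive pairs, via the inverted
    element -> sets index (each shared element contributes one 2-path in the
    bipartite set–element graph)."""
    elem_to_sets: dict[int, list[int]] = {}
    for i, members in enumerate(member_sets):
        if not alive[i]:
            continue
        for x in members:
            elem_to_sets.setdefault(x, []).append(i)
    inter: dict[tuple[int, int], int] = {}
    for sets in elem_to_sets.values():
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                key = (sets[a], sets[b])
                inter[key] = inter.get(key, 0) + 1
    return inter


def prune_clusters(
    clusters: list[Cluster], params: CorePeelParams
) -> list[Cluster]:
    """Phase IV: remove duplicates, strict subsets, and near-duplicates.

    Near-duplicates are pairs with Jaccard similarity > ``jaccard_max``;
    the smaller set is dropped, ties going against the set discovered later
    in Phase-I seed order.  Output preserves discovery order.
    """
    # duplicates: keep the first occurrence of each member set
    seen: set[frozenset[int]] = set()
    alive = [False] * len(clusters)
    for i, c in enumerate(clusters):
        if c.members not in seen:
            seen.add(c.members)
            alive[i] = True

    member_sets = [c.members for c in clusters]

    # subsets: visit sets in increasing size order; a set whose intersection
    # with some other alive set equals its own size is strictly contained
    inter = _pairwise_intersections(member_sets, alive)
    overlaps: dict[int, list[tuple[int, int]]] = {}
    for (a, b), cnt in inter.items():
        overlaps.setdefault(a, []).append((b, cnt))
        overlaps.setdefault(b, []).append((a, cnt))
    by_size = sorted(
        (i for i in range(len(clusters)) if alive[i]),
        key=lambda i: (len(member_sets[i]), i),
    )
    for j in by_size:
        for other, cnt in overlaps.get(j, ()):
            if (
                alive[other]
                and cnt == len(member_sets[j])
                and len(member_sets[other]) > len(member_sets[j])
            ):
                alive[j] = False
                break

    # near-duplicates by Jaccard
    inter = _pairwise_intersections(member_sets, alive)
    for (a, b), cnt in sorted(inter.items()):
        if not (alive[a] and alive[b]):
            continue
        union = len(member_sets[a]) + len(member_sets[b]) - cnt
        if cnt / union > params.jaccard_max:
            if len(member_sets[a]) < len(member_sets[b]):
                victim = a
            elif len(member_sets[b]) < len(member_sets[a]):
                victim = b
            else:
                victim = max(a, b)  # later in Phase-I seed order
            alive[victim] = False

    return [c for i, c in enumerate(clusters) if alive[i]]


def core_and_peel(g: Graph, params: CorePeelParams) -> list[Cluster]:
    """Run all four phases and return the pruned cluster list.

    Deterministic given (graph, parameters).  Every returned cluster has
    size >= q, induced density >= delta, contains its seed, and lies within
    the seed's closed 1-neighbourhood.
    """
    info = compute_core_info(g)
    clusters: list[Cluster] = []
    for v in order_vertices(g, info):
        s = candidate_set(g, info, v)
        if not passes_filter(g, s, params):
            continue
        cluster = peel(g, s, params, seed=v)
        if cluster is not None:
            clusters.append(cluster)
    return prune_clusters(clusters, params)
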