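"""Cluster-versus-gold-standard quality measures and diagnostics.

Predicted clusters P and curated complexes B (e.g. CYC2008, CORUM) are
compared with four scalar measures, each balancing precision against
recall in a different way:

* **F-measure** — a step-function match: a cluster counts as a hit when its
  precision-recall product PR(p, b) = |p∩b|^2 / (|p||b|) reaches a
  threshold omega (0.2 by default); F is the harmonic mean of the hit
  fractions on each side.
* **Jaccard measure** — size-weighted average of each set's best Jaccard
  coefficient on either side, harmonically combined.
* **PR measure** — same workflow with the PR product as the pair score.
* **Semantic similarity** — the fraction of a set's member pairs that are
  co-members of some set on the other side, size-weighted and harmonically
  combined; the only measure rewarding correct placement of proteins shared
  by several complexes.

Their sum is the Aggregated Score (AS), in [0, 4].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

from .graph import Graph, density, ego_coverage

__all__ = [
    "ClusterSet",
    "EvalResult",
    "pr_product",
    "jaccard_coefficient",
    "f_measure",
    "weighted_matching_measure",
    "semantic_similarity",
    "aggregated_score",
    "diagnostics",
]


@dataclass
class ClusterSet:
    """An ordered collection of protein-label sets with a provenance label."""

    sets: list[frozenset[str]]
    label: str = ""

    def __post_init__(self) -> None:
        self.sets = [frozenset(s) for s in self.sets]
        if any(not s for s in self.sets):
            raise ValueError("empty set in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restrict_to(self, universe: Iterable[str]) -> "ClusterSet":
        """Intersect every set with ``universe``, dropping emptied sets."""
        uni = set(universe)
        kept = [s & uni for s in self.sets]
        return ClusterSet([s for s in kept if s], label=self.label)

    def min_size(self, k: int) -> "ClusterSet":
        return ClusterSet([s for s in self.sets if len(s) >= k], label=self.label)

    @classmethod
    def from_clusters(
        cls, clusters: Sequence, g: Graph, label: str = "predicted"
    ) -> "ClusterSet":
        """Map predicted clusters (integer node indices) back to labels."""
        return cls([g.labels(c.members) for c in clusters], label=label)


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f_measure: float
    jaccard_measure: float
    pr_measure: float
    semantic_similarity: float
    aggregated_score: float

    def as_rows(self) -> list[tuple[str, float]]:
        return [
            ("precision", self.precision),
            ("recall", self.recall),
            ("f_measure", self.f_measure),
            ("jaccard_measure", self.jaccard_measure),
            ("pr_measure", self.pr_measure),
            ("semantic_similarity", self.semantic_similarity),
            ("aggregated_score", self.aggregated_score),
        ]


def pr_product(p: frozenset[str], b: frozenset[str]) -> float:
    """Precision-recall product |p∩b|^2 / (|p| * |b|)."""
    if not p or not b:
        raise ValueError("empty set")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


def jaccard_coefficient(p: frozenset[str], b: frozenset[str]) -> float:
    inter = len(p & b)
    if inter == 0:
        return 0.0
    return inter / (len(p) + len(b) - inter)


def _harmonic_mean(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def f_measure(
    P: ClusterSet, B: ClusterSet, omega: float = 0.2
) -> tuple[float, float, float]:
    """(precision, recall, F): hit fractions under the PR(p,b) >= omega rule.

    N_p clusters have some complex with PR >= omega, N_b complexes have some
    cluster with PR >= omega; precision = N_p/|P|, recall = N_b/|B|, F is
    their harmonic mean.
    """
    if len(P) == 0 or len(B) == 0:
        raise ValueError("empty collection")
    n_p = sum(1 for p in P if any(pr_product(p, b) >= omega for b in B))
    n_b = sum(1 for b in B if any(pr_product(p, b) >= omega for p in P))
    precision = n_p / len(P)
    recall = n_b / len(B)
    return precision, recall, _harmonic_mean(precision, recall)


def weighted_matching_measure(
    P: ClusterSet,
    B: ClusterSet,
    score: Callable[[frozenset[str], frozenset[str]], float],
) -> float:
    """Harmonic mean of the two size-weighted best-match averages.

    side(P) = sum_p |p| * max_b score(p, b) / sum_p |p|, symmetrically for B.
    With ``score=jaccard_coefficient`` this is the Jaccard measure; with
    ``score=pr_product`` the PR measure.
    """
    if len(P) == 0 or len(B) == 0:
        raise ValueError("empty collection")

    def side(X: ClusterSet, Y: ClusterSet) -> float:
        num = sum(len(x) * max(score(x, y) for y in Y) for x in X)
        return num / sum(len(x) for x in X)

    return _harmonic_mean(side(P, B), side(B, P))


def _co_membership_density(p: frozenset[str], other: ClusterSet) -> float:
    """Fraction of unordered member pairs of p co-occurring in a set of ``other``.

    Sets of size < 2 have no pairs and score 0 (degenerate predictions are
    penalised rather than skipped).
    """
    k = len(p)
    if k < 2:
        return 0.0
    membership: dict[str, list[int]] = {}
    for i, s in enumerate(other.sets):
        for x in p & s:
            membership.setdefault(x, []).append(i)
    hits = sum(
        1
        for x, y in combinations(sorted(p), 2)
        if x in membership
        and y in membership
        and not set(membership[x]).isdisjoint(membership[y])
    )
    return hits / (k * (k - 1) / 2)


def semantic_similarity(P: ClusterSet, B: ClusterSet) -> float:
    """Harmonic mean of the size-weighted co-membership densities.

    Density(P) = sum_p |p| * Den(p, B) / sum_p |p| where Den(p, B) is the
    fraction of p's member pairs found together in at least one gold
    complex; Density(B) symmetric.
    """
    if len(P) == 0 or len(B) == 0:
        raise ValueError("empty collection")

    def side(X: ClusterSet, Y: ClusterSet) -> float:
        num = sum(len(x) * _co_membership_density(x, Y) for x in X)
        return num / sum(len(x) for x in X)

    return _harmonic_mean(side(P, B), side(B, P))


def aggregated_score(P: ClusterSet, B: ClusterSet, omega: float = 0.2) -> EvalResult:
    """All four measures plus their sum, the Aggregated Score in [0, 4]."""
    precision, recall, f = f_measure(P, B, omega)
    jac = weighted_matching_measure(P, B, jaccard_coefficient)
    pr = weighted_matching_measure(P, B, pr_product)
    ss = semantic_similarity(P, B)
    return EvalResult(
        precision=precision,
        recall=recall,
        f_measure=f,
        jaccard_measure=jac,
        pr_measure=pr,
        semantic_similarity=ss,
        aggregated_score=f + jac + pr + ss,
    )


def diagnostics(g: Graph, B: ClusterSet, min_size: int = 3) -> dict[str, object]:
    """Structural statistics of a complex catalogue embedded in a PPIN.

    Complexes are restricted to proteins present in the graph; density and
    egocentricity statistics use only complexes of size >= ``min_size``
    (counts use strict inequalities).  The overlap histogram bins proteins
    by the number of complexes covering them: 1, 2, 3, more than 3.
    """
    restricted = [s & set(g.node_labels) for s in B.sets]
    big = [s for s in restricted if len(s) >= min_size]

    densities = []
    ego_09 = ego_05 = 0
    dens_09 = dens_05 = 0
    for s in big:
        idx = g.indices(s)
        d = density(g, idx)
        densities.append(d)
        if d > 0.9:
            dens_09 += 1
        if d > 0.5:
            dens_05 += 1
        cov = ego_coverage(g, idx)
        if cov >= 0.9:
            ego_09 += 1
        if cov >= 0.5:
            ego_05 += 1

    coverage: dict[str, int] = {}
    for s in restricted:
        for x in s:
            coverage[x] = coverage.get(x, 0) + 1
    overlap_hist = {"1": 0, "2": 0, "3": 0, ">3": 0}
    for cnt in coverage.values():
        if cnt == 1:
            overlap_hist["1"] += 1
        elif cnt == 2:
            overlap_hist["2"] += 1
        elif cnt == 3:
            overlap_hist["3"] += 1
        else:
            overlap_hist[">3"] += 1

    return {
        "n_complexes": len(big),
        "min_size": min(map(len, big)) if big else 0,
        "max_size": max(map(len, big)) if big else 0,
        "mean_size": (sum(map(len, big)) / len(big)) if big else 0.0,
        "density_gt_09": dens_09,
        "density_gt_05": dens_05,
        "ego_r1_ge_09": ego_09,
        "ego_r1_ge_05": ego_05,
        "covered_proteins": len(coverage),
        "overlap_hist": overlap_hist,
        "densities": densities,
    }
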