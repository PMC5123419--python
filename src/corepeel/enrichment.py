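"""Hypergeometric GO-enrichment of predicted clusters.

Each predicted cluster p is tested against every Gene Ontology class g it
intersects: the upper-tail hypergeometric probability H(M, p, g) that a
uniformly random subset of the background M of size |p| intersects g in at
least |p ∩ g| proteins.  The cluster is assigned the class of lowest
p-value, and the vector of per-cluster best p-values is corrected for
multiple testing with the Benjamini–Hochberg step-up procedure.  The
threshold sweep then counts clusters whose q-value falls below each of a
decreasing ladder of FDR thresholds.

Annotations are used as flat protein sets (no propagation along the GO
DAG).  p-values are evaluated in log space, so classes of extreme
enrichment (p down to ~1e-300) are resolved without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichmentRecord",
    "hypergeometric_pvalue",
    "best_class",
    "correct_fdr",
    "enrichment_sweep",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7)


@dataclass
class AnnotationSet:
    """GO classes as flat protein sets over a background universe M.

    By default the universe is the set of all annotated proteins in the
    loaded namespace — the natural background for asking whether a cluster
    is more functionally coherent than a random draw from the annotated
    proteome.
    """

    classes: dict[str, frozenset[str]]
    universe: frozenset[str]
    namespace: str = "BP"

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        for go_id, members in self.classes.items():
            if not members <= self.universe:
                raise ValueError(f"class {go_id} not contained in universe")


@dataclass(frozen=True)
class EnrichmentRecord:
    cluster_index: int
    go_id: str
    cluster_size: int
    intersection: int
    class_size: int
    p_value: float
    q_value: float | None = None


def _log_binom(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_pvalue(m_size: int, p_size: int, g_size: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(|X ∩ g| >= k).

    ``m_size`` is the background size |M|, ``p_size`` the cluster size,
    ``g_size`` the class size, ``k`` the observed intersection.  The sum
    over the tail is accumulated in log space (log-binomials via the log
    gamma function), keeping p-values finite and positive down to the
    1e-300 regime.
    """
    upper = min(p_size, g_size)
    if not (1 <= k <= upper <= m_size) or p_size > m_size or g_size > m_size:
        raise ValueError("invalid hypergeometric parameters")
    i = np.arange(k, upper + 1)
    log_terms = (
        _log_binom(g_size, i)
        + _log_binom(m_size - g_size, p_size - i)
        - _log_binom(m_size, p_size)
    )
    log_p = logsumexp(log_terms)
    return float(min(1.0, np.exp(log_p)))


def best_class(
    cluster: Iterable[str], ann: AnnotationSet, cluster_index: int = 0
) -> EnrichmentRecord | None:
    """Lowest-p-value class among those intersecting the cluster.

    Only the cluster members present in the background universe enter the
    test.  Ties are broken toward the lexicographically smaller GO id;
    returns None when no class intersects.
    """
    members = frozenset(cluster) & ann.universe
    if not members:
        return None
    m_size = len(ann.universe)
    best: EnrichmentRecord | None = None
    for go_id in sorted(ann.classes):
        g = ann.classes[go_id]
        k = len(members & g)
        if k == 0:
            continue
        p = hypergeometric_pvalue(m_size, len(members), len(g), k)
        if best is None or p < best.p_value:
            best = EnrichmentRecord(
                cluster_index=cluster_index,
                go_id=go_id,
                cluster_size=len(members),
                intersection=k,
                class_size=len(g),
                p_value=p,
            )
    return best


def correct_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (pi0 fixed to 1).

    Conservative relative to Storey's regularised estimate, so downstream
    threshold-sweep counts are lower bounds.  Output satisfies q_i >= p_i
    and is monotone in the order statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_clusters(
    clusters: Sequence[Iterable[str]], ann: AnnotationSet
) -> list[EnrichmentRecord]:
    """Best-class record for every cluster, with q-values across clusters.

    The multiple-testing correction is applied to the vector of per-cluster
    best p-values (one test per cluster); clusters intersecting no class
    are omitted.
    """
    records = []
    for i, cluster in enumerate(clusters):
        rec = best_class(cluster, ann, cluster_index=i)
        if rec is not None:
            records.append(rec)
    if not records:
        return []
    qvals = correct_fdr([r.p_value for r in records])
    return [
        EnrichmentRecord(
            cluster_index=r.cluster_index,
            go_id=r.go_id,
            cluster_size=r.cluster_size,
            intersection=r.intersection,
            class_size=r.class_size,
            p_value=r.p_value,
            q_value=float(q),
        )
        for r, q in zip(records, qvals)
    ]


def enrichment_sweep(
    clusters: Sequence[Iterable[str]],
    ann: AnnotationSet,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[float, int]:
    """Count of clusters with best-class q-value below each threshold.

    The counts are non-increasing as the threshold shrinks.
    """
    records = enrich_clusters(clusters, ann)
    return {
        t: sum(1 for r in records if r.q_value is not None and r.q_value < t)
        for t in thresholds
    }
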