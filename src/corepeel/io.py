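"""Readers and writers for edge lists, complex catalogues and GAF files.

Edge lists are tab/whitespace-separated text with two node-ID columns and
optionally a numeric confidence column (Biogrid / DIP / String-like
dialects); the String convention of dropping interactions with combined
score below 700 is expressed as a dialect with ``min_score=700``.
Complex catalogues are one complex per line, whitespace-separated protein
IDs, '#' comments.  GO annotations are read from GAF 2.x, keeping one
aspect and dropping the low-confidence evidence codes IEA, ND and NAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .algorithm import Cluster
from .enrichment import AnnotationSet
from .evaluation import ClusterSet
from .graph import Graph

__all__ = [
    "EdgeListDialect",
    "LoadReport",
    "read_edgelist",
    "write_edgelist",
    "read_complexes",
    "write_clusters",
    "read_gaf",
    "DEFAULT_EXCLUDED_EVIDENCE",
]

logger = logging.getLogger("corepeel")

DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA", "ND", "NAS"})

_ASPECT_BY_NAMESPACE = {"BP": "P", "CC": "C", "MF": "F"}


@dataclass(frozen=True)
class EdgeListDialect:
    """Column layout and filtering conventions of an edge-list file.

    ``min_score`` applies only when ``score_col`` is given; rows whose score
    falls below it are dropped (e.g. the String combined-score >= 700
    convention).
    """

    u_col: int = 0
    v_col: int = 1
    score_col: int | None = None
    min_score: float | None = None
    comment: str = "#"

    def __post_init__(self) -> None:
        if self.u_col == self.v_col:
            raise ValueError("endpoint columns must be distinct")
        if self.min_score is not None and self.score_col is None:
            raise ValueError("min_score requires a score column")


@dataclass
class LoadReport:
    total_rows: int = 0
    kept: int = 0
    dropped_comment: int = 0
    dropped_malformed: int = 0
    dropped_self_loop: int = 0
    dropped_low_score: int = 0
    dropped_duplicate: int = 0
    nodes: int = 0
    edges: int = 0

    @property
    def dropped(self) -> int:
        return (
            self.dropped_comment
            + self.dropped_malformed
            + self.dropped_self_loop
            + self.dropped_low_score
            + self.dropped_duplicate
        )


def read_edgelist(
    path: str | Path, dialect: EdgeListDialect = EdgeListDialect()
) -> tuple[Graph, LoadReport]:
    """Load an undirected simple graph from a tab-separated edge list.

    Self-loops are dropped, duplicate and reciprocal rows collapse to one
    undirected edge, and rows below the dialect's minimum score are
    discarded.  Malformed rows are logged and skipped.  Raises on an empty
    edge set.
    """
    report = LoadReport()
    g = Graph()
    needed = max(
        dialect.u_col,
        dialect.v_col,
        dialect.score_col if dialect.score_col is not None else 0,
    )
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            report.total_rows += 1
            if not line or line.startswith(dialect.comment):
                report.dropped_comment += 1
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) <= needed:
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                report.dropped_malformed += 1
                continue
            u, v = fields[dialect.u_col].strip(), fields[dialect.v_col].strip()
            if not u or not v:
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                report.dropped_malformed += 1
                continue
            if dialect.score_col is not None and dialect.min_score is not None:
                try:
                    score = float(fields[dialect.score_col])
                except ValueError:
                    logger.warning("%s:%d: bad score skipped", path, lineno)
                    report.dropped_malformed += 1
                    continue
                if score < dialect.min_score:
                    report.dropped_low_score += 1
                    continue
            if u == v:
                logger.warning("%s:%d: self-loop dropped", path, lineno)
                report.dropped_self_loop += 1
                continue
            before = g.m
            iu, iv = g._intern(u), g._intern(v)
            g.add_edge_idx(iu, iv)
            if g.m == before:
                report.dropped_duplicate += 1
            else:
                report.kept += 1
    g.n = len(g.node_labels)
    if g.m == 0:
        raise ValueError(f"no edges loaded from {path}")
    report.nodes, report.edges = g.n, g.m
    logger.info(
        "loaded %s: %d nodes, %d edges (%d rows dropped)",
        path,
        g.n,
        g.m,
        report.dropped,
    )
    return g, report


def write_edgelist(path: str | Path, g: Graph) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(g.edges_idx()):
            fh.write(f"{g.node_labels[u]}\t{g.node_labels[v]}\n")


def read_complexes(path: str | Path, label: str | None = None) -> ClusterSet:
    """One complex per line, whitespace/tab-separated protein IDs.

    Blank lines and '#' comments are ignored; duplicate complexes are
    preserved as given.
    """
    sets: list[frozenset[str]] = []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sets.append(frozenset(line.split()))
    return ClusterSet(sets, label=label or str(path))


def write_clusters(
    path: str | Path,
    clusters: ClusterSet | Sequence[Cluster],
    g: Graph | None = None,
    header: Iterable[str] = (),
) -> None:
    """Write one cluster per line (tab-separated member IDs, sorted).

    ``Cluster`` objects carry integer indices and need the graph for label
    mapping; a ``ClusterSet`` is written as-is.  ``header`` lines are
    emitted as '#' comments.
    """
    if isinstance(clusters, ClusterSet):
        rows = [sorted(s) for s in clusters]
    else:
        if g is None:
            raise ValueError("graph required to map cluster indices to labels")
        rows = [sorted(g.labels(c.members)) for c in clusters]
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_gaf(
    path: str | Path,
    namespace: str = "BP",
    excluded_evidence: frozenset[str] = DEFAULT_EXCLUDED_EVIDENCE,
    universe: Iterable[str] | None = None,
) -> AnnotationSet:
    """GO annotations from a GAF 2.x file, one aspect at a time.

    Keeps rows of the requested aspect (BP/CC/MF), drops the excluded
    evidence codes, and deduplicates repeated (protein, class) rows.  The
    background universe defaults to all annotated proteins retained in the
    namespace; pass ``universe`` to override (e.g. with the PPIN node set).
    """
    aspect = _ASPECT_BY_NAMESPACE.get(namespace.upper())
    if aspect is None:
        raise ValueError("namespace must be one of BP, CC, MF")
    classes: dict[str, set[str]] = {}
    annotated: set[str] = set()
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                logger.warning("malformed GAF row skipped")
                continue
            protein = fields[1].strip()
            go_id = fields[4].strip()
            evidence = fields[6].strip().upper()
            row_aspect = fields[8].strip().upper()
            if not protein or not go_id:
                continue
            if evidence in excluded_evidence or row_aspect != aspect:
                continue
            classes.setdefault(go_id, set()).add(protein)
            annotated.add(protein)
    if universe is not None:
        uni = frozenset(universe) | frozenset(annotated)
    else:
        uni = frozenset(annotated)
    return AnnotationSet(
        classes={k: frozenset(v) for k, v in sorted(classes.items())},
        universe=uni,
        namespace=namespace.upper(),
    )
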