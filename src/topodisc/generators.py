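"""Exhaustive generation of the two graph classes under study.

``connected_graphs(n)`` yields exactly one representative of every
isomorphism class of connected simple graphs on ``n`` vertices, and
``alkane_trees(n)`` one representative of every free tree on ``n`` vertices
whose maximum degree is at most four — the hydrogen-suppressed carbon
skeletons of the alkane isomers.

Connected graphs are produced by vertex augmentation: every graph on ``n``
vertices arises from some graph on ``n - 1`` vertices (possibly
disconnected) by attaching one new vertex with an arbitrary neighbourhood.
Candidates are de-duplicated with :func:`~topodisc.graph.canonical_certificate`
and the connected survivors are emitted in ascending certificate order, so
the enumeration is deterministic and reproducible.  Alkane trees come from
the constant-amortised-time free-tree generator (Wright–Richmond–
Odlyzko–McKay) behind :func:`networkx.nonisomorphic_trees`, filtered by the
degree bound, in the generator's own deterministic order.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterator, Literal

import networkx as _nx

from .graph import Graph, canonical_certificate

__all__ = [
    "GraphClassSpec",
    "enumerate_connected_graphs",
    "enumerate_alkane_trees",
    "class_cardinality",
    "MAX_ALKANE_DEGREE",
]

MAX_ALKANE_DEGREE = 4


@dataclass(frozen=True)
class GraphClassSpec:
    """A named exhaustive graph class: which family, and how many vertices."""

    kind: Literal["connected_graphs", "alkane_trees"]
    n: int

    def __post_init__(self):
        if self.kind not in ("connected_graphs", "alkane_trees"):
            raise ValueError(f"unknown graph class kind: {self.kind!r}")
        if self.n <= 0:
            raise ValueError("vertex count must be positive")

    def enumerate(self) -> Iterator[Graph]:
        if self.kind == "connected_graphs":
            return enumerate_connected_graphs(self.n)
        return enumerate_alkane_trees(self.n)

    def cardinality(self) -> int:
        return class_cardinality(self)

    def __str__(self) -> str:
        return f"{self.kind}(n={self.n})"


@functools.lru_cache(maxsize=None)
def _all_graphs_certs(n: int) -> tuple[tuple[tuple[tuple[int, int], ...], bytes], ...]:
    """All non-isomorphic simple graphs on n vertices (connected or not).

    Returns (edge-tuple, certificate) pairs sorted by certificate.  This is
    the augmentation base for level n + 1; disconnected graphs must be kept
    because a connected graph may only arise from one.
    """
    if n <= 0:
        raise ValueError("vertex count must be positive")
    if n == 1:
        g = Graph(1)
        return (((), canonical_certificate(g)),)
    seen: dict[bytes, tuple[tuple[int, int], ...]] = {}
    new = n - 1  # id of the augmenting vertex
    for edges, _cert in _all_graphs_certs(n - 1):
        for mask in range(1 << new):
            cand = edges + tuple(
                (i, new) for i in range(new) if mask >> i & 1
            )
            g = Graph(n, cand)
            cert = canonical_certificate(g)
            if cert not in seen:
                seen[cert] = cand
    return tuple(sorted(((e, c) for c, e in seen.items()), key=lambda t: t[1]))


def enumerate_connected_graphs(n: int) -> Iterator[Graph]:
    """All non-isomorphic connected simple graphs on ``n`` vertices.

    Deterministic: ascending canonical-certificate order.  Intended for
    desk-scale n (<= 8, i.e. 11,117 graphs); larger n works but the
    augmentation base grows steeply.
    """
    if n <= 0:
        raise ValueError("vertex count must be positive")
    for edges, _cert in _all_graphs_certs(n):
        g = Graph(n, edges)
        if g.is_connected():
            yield g


def enumerate_alkane_trees(n: int) -> Iterator[Graph]:
    """All non-isomorphic free trees on ``n`` vertices with max degree <= 4.

    Streams in the deterministic order of the underlying free-tree
    generator; constant memory per tree, suitable for the 10^5-tree classes
    (n = 19 has 148,284 members).
    """
    if n <= 0:
        raise ValueError("vertex count must be positive")
    if n == 1:
        yield Graph(1)
        return
    if n == 2:
        yield Graph(2, [(0, 1)])
        return
    for t in _nx.nonisomorphic_trees(n):
        if max(d for _, d in t.degree()) <= MAX_ALKANE_DEGREE:
            yield Graph.from_networkx(t)


@functools.lru_cache(maxsize=None)
def class_cardinality(spec: GraphClassSpec) -> int:
    """Number of graphs in the class, by running the enumeration."""
    return sum(1 for _ in spec.enumerate())
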