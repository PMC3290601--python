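"""Core graph type and metric/symmetry primitives.

The whole package works on simple, undirected, unweighted graphs with
vertices labelled ``0..n-1``.  :class:`Graph` is a thin immutable container;
metric primitives (distance matrix, j-spheres, diameter) and symmetry
primitives (automorphism orbits, canonical certificates) are free functions
so that every descriptor module shares one vocabulary.

Distances and canonical labelling are delegated to :mod:`igraph` (BLISS
backend); graph6 encoding/decoding is delegated to :mod:`networkx`.
"""

from __future__ import annotations

import functools
from typing import Iterable, Iterator, Sequence

import igraph as _ig
import networkx as _nx
import numpy as np

__all__ = [
    "Graph",
    "GraphNotConnectedError",
    "Graph6ParseError",
    "distance_matrix",
    "distance_sums",
    "diameter",
    "j_sphere_sizes",
    "cyclomatic_number",
    "vertex_orbits",
    "canonical_certificate",
    "read_graph6",
    "write_graph6",
    "read_edgelist",
]


class GraphNotConnectedError(ValueError):
    """Raised when a distance-based operation receives a disconnected graph."""


class Graph6ParseError(ValueError):
    """Raised on malformed graph6 input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class Graph:
    """Simple undirected unweighted graph on vertices ``0..n-1``.

    Parameters
    ----------
    n:
        Number of vertices.
    edges:
        Iterable of vertex pairs.  Pairs are normalised to ``(min, max)``;
        duplicates collapse.  Self-loops and out-of-range endpoints raise
        ``ValueError``.
    """

    __slots__ = ("n", "edges", "_igraph", "_dist", "_cert")

    def __init__(self, n: int, edges: Iterable[tuple[int, int]] = ()):
        if n < 0:
            raise ValueError("vertex count must be non-negative")
        norm = set()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop ({u},{v}) not allowed")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) out of range for n={n}")
            norm.add((u, v) if u < v else (v, u))
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "edges", frozenset(norm))
        object.__setattr__(self, "_igraph", None)
        object.__setattr__(self, "_dist", None)
        object.__setattr__(self, "_cert", None)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("Graph is immutable")

    # -- basic counts ------------------------------------------------------

    @property
    def m(self) -> int:
        """Edge count."""
        return len(self.edges)

    def degree(self, v: int | None = None):
        degs = [0] * self.n
        for u, w in self.edges:
            degs[u] += 1
            degs[w] += 1
        return degs if v is None else degs[v]

    # -- conversions -------------------------------------------------------

    def to_igraph(self) -> _ig.Graph:
        if self._igraph is None:
            g = _ig.Graph(self.n, sorted(self.edges))
            object.__setattr__(self, "_igraph", g)
        return self._igraph

    def to_networkx(self) -> _nx.Graph:
        g = _nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: _nx.Graph) -> "Graph":
        nodes = sorted(g.nodes())
        idx = {v: i for i, v in enumerate(nodes)}
        return cls(len(nodes), ((idx[u], idx[v]) for u, v in g.edges()))

    # -- predicates --------------------------------------------------------

    def is_connected(self) -> bool:
        if self.n == 0:
            return False
        return self.to_igraph().is_connected()

    def is_tree(self) -> bool:
        return self.is_connected() and self.m == self.n - 1

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Graph)
            and self.n == other.n
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.n, self.edges))

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, m={self.m})"


def _require_connected(g: Graph) -> None:
    if not g.is_connected():
        raise GraphNotConnectedError("graph not connected")


def distance_matrix(g: Graph) -> np.ndarray:
    """All-pairs shortest-path matrix of a connected graph.

    Returns an ``(n, n)`` integer array with zero diagonal; raises
    :class:`GraphNotConnectedError` on disconnected input (infinite
    distances are never encoded).
    """
    if g._dist is None:
        _require_connected(g)
        d = np.asarray(g.to_igraph().distances(), dtype=float)
        object.__setattr__(g, "_dist", d.astype(np.int64))
    return g._dist


def distance_sums(g: Graph) -> np.ndarray:
    """Row sums s_v of the distance matrix (the vertex distance degrees)."""
    return distance_matrix(g).sum(axis=1)


def diameter(g: Graph) -> int:
    """Largest shortest-path distance rho(G)."""
    return int(distance_matrix(g).max())


def j_sphere_sizes(g: Graph, v: int) -> np.ndarray:
    """Cardinalities |S_j(v)| of the j-spheres of ``v`` for j = 1..rho(G).

    The vector always has length ``rho(G)``; entries beyond the
    eccentricity of ``v`` are zero, and the entries sum to ``n - 1``.
    """
    if not (0 <= v < g.n):
        raise ValueError(f"vertex {v} out of range for n={g.n}")
    d = distance_matrix(g)
    rho = int(d.max())
    row = d[v]
    counts = np.bincount(row[row > 0], minlength=rho + 1)[1 : rho + 1]
    return counts.astype(np.int64)


def cyclomatic_number(g: Graph) -> int:
    """mu = m - n + 1, the number of independent cycles of a connected graph."""
    _require_connected(g)
    return g.m - g.n + 1


def vertex_orbits(g: Graph) -> list[list[int]]:
    """Partition of the vertices into automorphism orbits.

    Two vertices land in the same block iff some automorphism of ``g`` maps
    one onto the other.  Orbits are derived from the generators of the
    automorphism group (BLISS); blocks are sorted, and listed by their
    smallest member.
    """
    if g.n == 0:
        return []
    gens = g.to_igraph().automorphism_group()
    parent = list(range(g.n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in gens:
        for v in range(g.n):
            a, b = find(v), find(perm[v])
            if a != b:
                parent[a] = b
    blocks: dict[int, list[int]] = {}
    for v in range(g.n):
        blocks.setdefault(find(v), []).append(v)
    return sorted((sorted(b) for b in blocks.values()), key=lambda b: b[0])


def canonical_certificate(g: Graph) -> bytes:
    """Deterministic byte string equal for two graphs iff they are isomorphic.

    The BLISS canonical permutation is applied and the relabelled
    upper-triangular adjacency bitset is packed behind a leading vertex-count
    byte, so certificates of graphs of different order never collide.
    """
    if g._cert is None:
        perm = g.to_igraph().canonical_permutation()
        bits = 0
        for u, v in g.edges:
            a, b = perm[u], perm[v]
            if a > b:
                a, b = b, a
            bits |= 1 << (b * (b - 1) // 2 + a)
        nbytes = (g.n * (g.n - 1) // 2 + 7) // 8
        cert = bytes([g.n]) + bits.to_bytes(nbytes, "big")
        object.__setattr__(g, "_cert", cert)
    return g._cert


# ---------------------------------------------------------------------------
# graph6 and edge-list I/O


_G6_HEADER = b">>graph6<<"


def read_graph6(stream) -> Iterator[Graph]:
    """Iterate :class:`Graph` objects from a graph6 file object or path.

    Accepts the optional ``>>graph6<<`` header; vertex order of each line is
    preserved.  Malformed lines raise :class:`Graph6ParseError` with the
    offending line number.
    """
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream, "rb")
        close = True
    try:
        for lineno, raw in enumerate(stream, start=1):
            if isinstance(raw, str):
                raw = raw.encode("ascii")
            line = raw.strip()
            if line.startswith(_G6_HEADER):
                line = line[len(_G6_HEADER):]
            if not line:
                continue
            try:
                nxg = _nx.from_graph6_bytes(line)
            except (_nx.NetworkXError, ValueError, UnicodeDecodeError) as exc:
                raise Graph6ParseError(lineno, str(exc)) from exc
            yield Graph(nxg.number_of_nodes(), nxg.edges())
    finally:
        if close:
            stream.close()


def write_graph6(stream, graphs: Iterable[Graph]) -> int:
    """Write graphs one per line in graph6; returns the number written."""
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream, "wb")
        close = True
    try:
        count = 0
        for g in graphs:
            stream.write(_nx.to_graph6_bytes(g.to_networkx(), header=False))
            count += 1
        return count
    finally:
        if close:
            stream.close()


def read_edgelist(stream) -> Graph:
    """Read one graph from a whitespace-separated edge list.

    The first non-comment content must be a ``#n=<N>`` header giving the
    vertex count (isolated vertices are otherwise unrepresentable); each
    following line is ``u v``.
    """
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream, "r")
        close = True
    try:
        n = None
        edges = []
        for raw in stream:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].replace(" ", "")
                if body.startswith("n="):
                    n = int(body[2:])
                continue
            u, v = line.split()
            edges.append((int(u), int(v)))
        if n is None:
            raise ValueError("edge-list input lacks the '#n=<N>' header")
        return Graph(n, edges)
    finally:
        if close:
            stream.close()


# small named graphs used throughout the tests and docs ---------------------


def path_graph(n: int) -> Graph:
    return Graph(n, ((i, i + 1) for i in range(n - 1)))


def cycle_graph(n: int) -> Graph:
    return Graph(n, [(i, (i + 1) % n) for i in range(n)])


def complete_graph(n: int) -> Graph:
    return Graph(n, ((i, j) for i in range(n) for j in range(i + 1, n)))


def star_graph(n: int) -> Graph:
    """Star K_{1,n-1} with vertex 0 at the centre."""
    return Graph(n, ((0, i) for i in range(1, n)))
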