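"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library machinery they are used to
check: orbits and automorphism counts come from explicit permutation
search, isomorphism classes from pairwise VF2 matching in networkx, and
class cardinalities from closed-form labelled counts (connected-graph
recurrence; bounded-degree Pruefer-sequence counting).
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import permutations, product

import networkx as nx
import pytest

from topodisc import Graph


# ---------------------------------------------------------------------------
# small named graphs


@pytest.fixture
def p3():
    return Graph(3, [(0, 1), (1, 2)])


@pytest.fixture
def p4():
    return Graph(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def k3():
    return Graph(3, [(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def c4():
    return Graph(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def star4():
    """K_{1,3}, centre vertex 0."""
    return Graph(4, [(0, 1), (0, 2), (0, 3)])


# ---------------------------------------------------------------------------
# brute-force symmetry oracles


def brute_force_orbits(g: Graph) -> list[list[int]]:
    """Vertex orbits by explicit search over all n! permutations."""
    adj = g.edges
    autos = []
    for perm in permutations(range(g.n)):
        if all(
            ((perm[u], perm[v]) if perm[u] < perm[v] else (perm[v], perm[u])) in adj
            for u, v in adj
        ):
            autos.append(perm)
    parent = list(range(g.n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for perm in autos:
        for v in range(g.n):
            a, b = find(v), find(perm[v])
            if a != b:
                parent[a] = b
    blocks: dict[int, list[int]] = {}
    for v in range(g.n):
        blocks.setdefault(find(v), []).append(v)
    return sorted((sorted(b) for b in blocks.values()), key=lambda b: b[0])


def brute_force_automorphism_count(g: Graph) -> int:
    adj = g.edges
    return sum(
        1
        for perm in permutations(range(g.n))
        if all(
            ((perm[u], perm[v]) if perm[u] < perm[v] else (perm[v], perm[u])) in adj
            for u, v in adj
        )
    )


def dedup_isomorphism_classes(graphs) -> list[nx.Graph]:
    """Pairwise-VF2 de-duplication (networkx), degree-sequence prefiltered."""
    buckets: dict[tuple, list[nx.Graph]] = {}
    for g in graphs:
        key = tuple(sorted(d for _, d in g.degree()))
        reps = buckets.setdefault(key, [])
        if not any(nx.is_isomorphic(g, r) for r in reps):
            reps.append(g)
    return [g for reps in buckets.values() for g in reps]


# ---------------------------------------------------------------------------
# closed-form labelled counts


def labeled_connected_graph_count(n: int) -> int:
    """Number of connected labelled graphs on n vertices, by the classical
    recurrence C_n = 2^C(n,2) - sum_k C(n-1, k-1) C_k 2^C(n-k, 2)."""
    C = [0, 1]
    for m in range(2, n + 1):
        total = 2 ** (m * (m - 1) // 2)
        for k in range(1, m):
            total -= math.comb(m - 1, k - 1) * C[k] * 2 ** ((m - k) * (m - k - 1) // 2)
        C.append(total)
    return C[n]


def labeled_bounded_degree_tree_count(n: int, max_degree: int = 4) -> int:
    """Number of labelled trees on n vertices with max degree <= max_degree.

    A vertex of degree d appears exactly d-1 times in the Pruefer sequence,
    so this is the number of length-(n-2) sequences over n symbols in which
    no symbol occurs more than max_degree - 1 times:
    (n-2)! * [x^(n-2)] (sum_{i=0}^{max_degree-1} x^i / i!)^n.
    """
    if n == 1:
        return 1
    L = n - 2
    # polynomial coefficients of (sum x^i/i!)^n up to x^L, exact rationals
    base = [Fraction(1, math.factorial(i)) for i in range(max_degree)]
    poly = [Fraction(1)]
    for _ in range(n):
        new = [Fraction(0)] * (min(len(poly) + len(base) - 1, L + 1))
        for i, a in enumerate(poly):
            if i > L:
                break
            for j, b in enumerate(base):
                if i + j <= L:
                    new[i + j] += a * b
        poly = new
    count = poly[L] * math.factorial(L)
    assert count.denominator == 1
    return int(count)


def prufer_alkane_classes(n: int, max_degree: int = 4) -> list[nx.Graph]:
    """All degree-bounded free trees on n vertices, from exhaustive Pruefer
    enumeration plus pairwise-isomorphism rejection (n <= 7 intended)."""
    if n == 1:
        return [nx.empty_graph(1)]
    if n == 2:
        return [nx.path_graph(2)]
    trees = []
    for seq in product(range(n), repeat=n - 2):
        counts = [0] * n
        for s in seq:
            counts[s] += 1
        if max(counts) > max_degree - 1:
            continue
        trees.append(nx.from_prufer_sequence(list(seq)))
    return dedup_isomorphism_classes(trees)
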