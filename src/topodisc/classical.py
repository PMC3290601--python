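"""Classical (non-functional) topological indices behind one registry.

Twenty descriptors spanning the main families used in descriptor-degeneracy
studies: distance-based connectivity indices (Balaban J and its two
information-weighted variants), magnitude-based distance entropies,
partition entropies (orbits, degrees, eccentricities), and plain
degree/adjacency sums.  ``classical_index(name, g)`` evaluates one by
registry key; integer-valued indices return exact ``int``.

Several of the less common formulas circulate in more than one variant; the
convention adopted here is recorded in each descriptor's ``provenance``
string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .graph import Graph, distance_matrix, vertex_orbits

__all__ = [
    "IndexDescriptor",
    "CLASSICAL_INDICES",
    "classical_index",
    "balaban_j",
    "partition_entropy",
    "partition_entropy_total",
]


@dataclass(frozen=True)
class IndexDescriptor:
    name: str
    func: Callable[[Graph], float]
    kind: str  # "integer" | "real"
    provenance: str


def partition_entropy(block_sizes) -> float:
    """Mean entropy -sum (n_i/N) log2 (n_i/N) of a partition into blocks.

    Zero for a single block, log2 N when all blocks are singletons.
    """
    sizes = sorted(int(b) for b in block_sizes)  # order-independent summation
    if not sizes or sizes[0] <= 0:
        raise ValueError("block sizes must be positive")
    total = sum(sizes)
    return -sum(b / total * math.log2(b / total) for b in sizes)


def partition_entropy_total(block_sizes) -> float:
    """Total-information companion N log2 N - sum n_i log2 n_i."""
    sizes = sorted(int(b) for b in block_sizes)
    if not sizes or sizes[0] <= 0:
        raise ValueError("block sizes must be positive")
    total = sum(sizes)
    return total * math.log2(total) - sum(b * math.log2(b) for b in sizes)


def _distance_sums(g: Graph) -> np.ndarray:
    return distance_matrix(g).sum(axis=1)


def _require_edges(g: Graph) -> None:
    if g.n < 2:
        raise ValueError("distance-based index undefined for a single vertex")


def _balaban_form(g: Graph, weights: np.ndarray) -> float:
    """(m / (mu + 1)) * sum over edges of (w_u w_v)^(-1/2).

    Edge terms are summed in sorted order so that graphs with identical
    weight multisets produce bit-identical values.
    """
    if np.any(weights <= 0):
        raise ValueError("Balaban-type index needs positive vertex weights")
    m = g.m
    mu = m - g.n + 1
    terms = sorted(1.0 / math.sqrt(weights[u] * weights[v]) for u, v in g.edges)
    return m / (mu + 1.0) * sum(terms)


def balaban_j(g: Graph) -> float:
    """Balaban's distance-connectivity index J.

    J = (m / (mu + 1)) * sum_{(u,v) in E} (s_u s_v)^(-1/2), with s_v the
    distance-matrix row sums and mu the cyclomatic number.
    """
    _require_edges(g)
    return _balaban_form(g, _distance_sums(g).astype(float))


def _distance_info_weights(g: Graph) -> np.ndarray:
    """u_v = s_v log2 s_v - sum_j g_vj * j log2 j, the total information on
    the distance magnitudes seen from v."""
    d = distance_matrix(g)
    s = d.sum(axis=1).astype(float)
    rho = int(d.max())
    jlog = np.array([j * math.log2(j) if j > 1 else 0.0 for j in range(rho + 1)])
    u = np.empty(g.n)
    for v in range(g.n):
        counts = np.bincount(d[v], minlength=rho + 1)
        u[v] = s[v] * math.log2(s[v]) - float(np.dot(counts, jlog))
    return u


def balaban_like_1(g: Graph) -> float:
    """J-type index over total distance-information vertex weights u_v."""
    _require_edges(g)
    if g.n < 3:
        raise ValueError("distance-information weights vanish for n < 3")
    return _balaban_form(g, _distance_info_weights(g))


def balaban_like_2(g: Graph) -> float:
    """J-type index over mean distance-information weights u_v / s_v."""
    _require_edges(g)
    if g.n < 3:
        raise ValueError("distance-information weights vanish for n < 3")
    s = _distance_sums(g).astype(float)
    return _balaban_form(g, _distance_info_weights(g) / s)


def _distance_pair_counts(g: Graph) -> np.ndarray:
    """g_j = number of unordered vertex pairs at distance j, j = 0..rho."""
    d = distance_matrix(g)
    rho = int(d.max())
    iu = np.triu_indices(g.n, k=1)
    return np.bincount(d[iu], minlength=rho + 1)


def bonchev_magnitude_total(g: Graph) -> float:
    """Magnitude-based information on distances, total form:
    W log2 W - sum_j g_j * j log2 j (W the Wiener index)."""
    _require_edges(g)
    gj = _distance_pair_counts(g)
    W = float(sum(j * c for j, c in enumerate(gj)))
    return W * math.log2(W) - sum(
        c * j * math.log2(j) for j, c in enumerate(gj) if j > 1 and c
    )


def bonchev_magnitude_mean(g: Graph) -> float:
    """Magnitude-based information on distances, mean form:
    -sum_j (j g_j / W) log2 (j g_j / W)."""
    _require_edges(g)
    gj = _distance_pair_counts(g)
    W = float(sum(j * c for j, c in enumerate(gj)))
    out = 0.0
    for j, c in enumerate(gj):
        if j and c:
            q = j * c / W
            out -= q * math.log2(q)
    return out


def compactness(g: Graph) -> float:
    """Wiener-based compactness 4W / (n(n-1))."""
    _require_edges(g)
    W = distance_matrix(g).sum() / 2.0
    return 4.0 * W / (g.n * (g.n - 1))


def complexity_index_b(g: Graph) -> float:
    """Bonchev's complexity index B = sum_v deg(v) / s_v."""
    _require_edges(g)
    s = _distance_sums(g)
    deg = g.degree()
    return float(sum(deg[v] / s[v] for v in range(g.n)))


def vertex_complexity(g: Graph) -> float:
    """Mean vertex entropy of the distance-count distributions,
    H^V = (1/n) sum_v [ -sum_j (k_vj / n) log2 (k_vj / n) ], where k_vj
    counts vertices at distance j from v (j = 0 included)."""
    _require_edges(g)
    d = distance_matrix(g)
    rho = int(d.max())
    total = 0.0
    for v in range(g.n):
        counts = np.bincount(d[v], minlength=rho + 1)
        total += partition_entropy([c for c in counts if c])
    return total / g.n


def harary(g: Graph) -> float:
    """Harary index, sum over pairs of reciprocal distances."""
    _require_edges(g)
    d = distance_matrix(g)
    iu = np.triu_indices(g.n, k=1)
    return float((1.0 / d[iu]).sum())


def hyper_distance_path(g: Graph) -> int:
    """Hyper-distance-path index W + sum over pairs of C(d,2)
    (= sum over pairs of (d^2 + d)/2; integer-valued)."""
    _require_edges(g)
    d = distance_matrix(g)
    iu = np.triu_indices(g.n, k=1)
    dd = d[iu].astype(object)
    return int(sum(dd) + sum(x * (x - 1) // 2 for x in dd))


def konstantinova_vertex_entropy_sum(g: Graph) -> float:
    """Sum of local vertex entropies of the distance magnitudes:
    sum_v [ -sum_{u != v} (d(v,u)/s_v) log2 (d(v,u)/s_v) ]."""
    _require_edges(g)
    d = distance_matrix(g)
    s = d.sum(axis=1).astype(float)
    total = 0.0
    for v in range(g.n):
        p = d[v][d[v] > 0] / s[v]
        total += float(-(p * np.log2(p)).sum())
    return total


def normalized_edge_complexity(g: Graph) -> float:
    """Total adjacency normalised by n^2: E_N = 2m / n^2."""
    return 2 * g.m / g.n**2


def prs(g: Graph) -> int:
    """Product of the distance-matrix row sums (exact integer)."""
    _require_edges(g)
    out = 1
    for s in _distance_sums(g):
        out *= int(s)
    return out


def radial_centric(g: Graph) -> float:
    """Mean entropy of the eccentricity partition of the vertices."""
    _require_edges(g)
    ecc = distance_matrix(g).max(axis=1)
    counts = np.bincount(ecc)
    return partition_entropy([c for c in counts if c])


def topological_info_content(g: Graph) -> float:
    """Mean entropy of the automorphism-orbit partition (Mowshowitz)."""
    return partition_entropy([len(b) for b in vertex_orbits(g)])


def total_adjacency(g: Graph) -> int:
    """Sum of the adjacency matrix, 2m."""
    return 2 * g.m


def degree_information(g: Graph) -> float:
    """Mean entropy of the vertex-degree partition."""
    counts = np.bincount(g.degree(), minlength=1)
    return partition_entropy([c for c in counts if c])


def bertz(g: Graph) -> float:
    """Bertz connection-based complexity: with n_v = C(deg v, 2) the number
    of two-edge paths centred at v and N their total,
    C = N log2 N - sum_v n_v log2 n_v."""
    deg = g.degree()
    nv = [d * (d - 1) // 2 for d in deg]
    N = sum(nv)
    if N == 0:
        return 0.0
    return partition_entropy_total([x for x in nv if x])


def zagreb1(g: Graph) -> int:
    """First Zagreb index, sum of squared degrees."""
    return int(sum(d * d for d in g.degree()))


def zagreb2(g: Graph) -> int:
    """Second Zagreb index, sum of deg(u) deg(v) over edges."""
    deg = g.degree()
    return int(sum(deg[u] * deg[v] for u, v in g.edges))


_REGISTRY: tuple[IndexDescriptor, ...] = (
    IndexDescriptor("balaban_j", balaban_j, "real",
                    "distance-connectivity J over distance sums s_v"),
    IndexDescriptor("balaban_like_1", balaban_like_1, "real",
                    "J-form over u_v = s_v log2 s_v - sum_j g_vj j log2 j "
                    "(total information on distance magnitudes)"),
    IndexDescriptor("balaban_like_2", balaban_like_2, "real",
                    "J-form over mean information weights u_v / s_v"),
    IndexDescriptor("bertz", bertz, "real",
                    "connection (two-edge path) total information; adopted "
                    "convention: classes = connections grouped by centre vertex"),
    IndexDescriptor("bonchev_magnitude_mean", bonchev_magnitude_mean, "real",
                    "mean magnitude-based information on distances"),
    IndexDescriptor("bonchev_magnitude_total", bonchev_magnitude_total, "real",
                    "total magnitude-based information on distances"),
    IndexDescriptor("compactness", compactness, "real",
                    "4W/(n(n-1)); adopted among the circulating normalisations "
                    "of Wiener-based compactness"),
    IndexDescriptor("complexity_index_b", complexity_index_b, "real",
                    "B = sum_v deg(v)/s_v"),
    IndexDescriptor("vertex_complexity", vertex_complexity, "real",
                    "mean vertex entropy of distance-count distributions "
                    "(distance-0 class included)"),
    IndexDescriptor("harary", harary, "real", "sum of reciprocal distances"),
    IndexDescriptor("hyper_distance_path", hyper_distance_path, "integer",
                    "W + sum_pairs C(d,2)"),
    IndexDescriptor("konstantinova_vertex_entropy_sum",
                    konstantinova_vertex_entropy_sum, "real",
                    "sum of local distance-magnitude entropies"),
    IndexDescriptor("normalized_edge_complexity", normalized_edge_complexity,
                    "real", "2m/n^2"),
    IndexDescriptor("prs", prs, "integer", "product of distance row sums"),
    IndexDescriptor("radial_centric", radial_centric, "real",
                    "eccentricity-partition mean entropy"),
    IndexDescriptor("topological_info_content", topological_info_content, "real",
                    "automorphism-orbit-partition mean entropy"),
    IndexDescriptor("total_adjacency", total_adjacency, "integer", "2m"),
    IndexDescriptor("degree_information", degree_information, "real",
                    "degree-partition mean entropy"),
    IndexDescriptor("zagreb1", zagreb1, "integer", "sum deg^2"),
    IndexDescriptor("zagreb2", zagreb2, "integer", "sum_E deg deg"),
)

CLASSICAL_INDICES: dict[str, IndexDescriptor] = {d.name: d for d in _REGISTRY}


def classical_index(name: str, g: Graph) -> float:
    """Evaluate a registered classical index on ``g``."""
    try:
        desc = CLASSICAL_INDICES[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; available: {', '.join(sorted(CLASSICAL_INDICES))}"
        ) from None
    return desc.func(g)
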