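"""Graph entropies from information functionals.

An *information functional* assigns every vertex a positive weight f(v)
capturing local structure; normalising gives vertex probabilities
p(v) = f(v) / sum_u f(u) and the graph entropy

    I_f(G) = - sum_v p(v) log2 p(v)        (bits, in [0, log2 n]),

together with its information distance lambda * (log2 n - I_f(G)) from the
maximum.  Three functionals are implemented:

``f_V``  (j-sphere functional)
    f_V(v) = sum_j c_j |S_j(v)|, where |S_j(v)| is the number of vertices at
    distance exactly j from v.

``f_P``  (path functional)
    f_P(v) = sum_j c_j sigma_j(v), where sigma_j(v) counts the shortest
    paths of length j starting at v (all geodesics, not one per target).
    On trees sigma_j = |S_j|, so f_P coincides with f_V there.

``f_rho``  (degree-degree association functional)
    For each shortest path p = (v = v_0, ..., v_j) starting at v, take the
    total variation of its degree sequence, sum over the level-j paths to
    get lambda_j(v), and set

        f_rho(v) = alpha ** ( sum_j c_j * lambda_j(v) ),   alpha > 0.

    The exponential composition keeps f_rho strictly positive on every
    graph, including regular graphs where all degree differences vanish.
    Entropies are evaluated in log space, so extreme weight ratios cannot
    overflow.

The level weights c_1..c_rho(G) come from a coefficient scheme: ``lin``
(c_j = rho - j + 1), ``quad`` (c_j = (rho - j + 1)^2), ``exp``
(c_j = e^(rho - j)), or ``custom``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .graph import Graph, distance_matrix

__all__ = [
    "CoefficientScheme",
    "VertexFunctional",
    "scheme_coefficients",
    "functional_fV",
    "functional_fP",
    "functional_frho",
    "functional_frho_linear",
    "frho_level_variations",
    "entropy_from_functional",
    "entropy_distance",
    "DEFAULT_FRHO_ALPHA",
    "ENTROPY_INDICES",
]

#: Default base of the degree-degree association functional.  alpha < 1
#: gives low weight to high-variation vertices; the magnitude is moderate so
#: that double-precision entropies are exact at the grouping precision used
#: by the uniqueness pipeline (see docs/methods.md, numerical choices).
DEFAULT_FRHO_ALPHA: float = 2.0 ** -0.5

_PRESETS = ("lin", "quad", "exp")


@dataclass(frozen=True)
class CoefficientScheme:
    """Positive level weights c_1..c_rho, materialised for one diameter."""

    name: str
    coefficients: tuple[float, ...]

    def __post_init__(self):
        c = self.coefficients
        if len(c) == 0:
            raise ValueError("coefficient vector must be non-empty")
        if any(x <= 0 for x in c):
            raise ValueError("coefficients must be strictly positive")
        if len(c) > 1 and len(set(c)) < 2:
            raise ValueError("at least two coefficients must be distinct")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)


def scheme_coefficients(
    name: str, rho: int, custom: Sequence[float] | None = None
) -> CoefficientScheme:
    """Materialise a coefficient scheme for a graph of diameter ``rho``.

    For ``rho == 1`` (complete graphs) the vector has a single entry; the
    two-distinct-coefficients rule is waived there because the entropy is
    forced to log2 n regardless of the weight.
    """
    if rho < 1:
        raise ValueError("diameter must be at least 1")
    js = np.arange(1, rho + 1)
    if name == "lin":
        c = (rho - js + 1).astype(float)
    elif name == "quad":
        c = ((rho - js + 1) ** 2).astype(float)
    elif name == "exp":
        c = np.exp((rho - js).astype(float))
    elif name == "custom":
        if custom is None:
            raise ValueError("custom scheme requires an explicit vector")
        if len(custom) != rho:
            raise ValueError(f"custom vector must have length rho={rho}")
        c = np.asarray(custom, dtype=float)
    else:
        raise ValueError(f"unknown scheme {name!r}; choose from {_PRESETS} or 'custom'")
    return CoefficientScheme(name, tuple(float(x) for x in c))


@dataclass(frozen=True)
class VertexFunctional:
    """Per-vertex positive weights of one information functional.

    ``log_values`` always holds ln f(v); ``values`` additionally holds the
    raw weights when they are representable (the sphere and path functionals
    produce small numbers, the degree-degree association functional may
    not).  Entropies are computed from whichever representation is exact.
    """

    name: str
    scheme: str
    log_values: np.ndarray
    values: np.ndarray | None = None

    def __post_init__(self):
        if self.values is not None and np.any(self.values <= 0):
            raise ValueError(
                f"functional {self.name!r} produced a non-positive vertex value"
            )

    @property
    def n(self) -> int:
        return len(self.log_values)

    def probabilities(self) -> np.ndarray:
        """p(v) = f(v) / sum f(u), computed stably."""
        if self.values is not None:
            return self.values / self.values.sum()
        x = self.log_values - self.log_values.max()
        w = np.exp(x)
        return w / w.sum()


def _geodesic_counts(g: Graph, v: int, d: np.ndarray) -> np.ndarray:
    """sigma[u] = number of shortest v-u paths, by BFS-layer dynamic programming."""
    n = g.n
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in g.edges:
        adj[a].append(b)
        adj[b].append(a)
    sigma = np.zeros(n, dtype=np.int64)
    sigma[v] = 1
    row = d[v]
    for u in np.argsort(row, kind="stable"):
        if u == v:
            continue
        sigma[u] = sum(sigma[w] for w in adj[u] if row[w] == row[u] - 1)
    return sigma


def _resolve_scheme(g: Graph, scheme) -> tuple[np.ndarray, int, str]:
    d = distance_matrix(g)
    rho = int(d.max())
    if rho < 1:
        raise ValueError("functional undefined for a single-vertex graph")
    if isinstance(scheme, str):
        scheme = scheme_coefficients(scheme, rho)
    elif len(scheme.coefficients) != rho:
        raise ValueError(
            f"scheme has {len(scheme.coefficients)} coefficients, graph diameter is {rho}"
        )
    return scheme.as_array(), rho, scheme.name


def functional_fV(g: Graph, scheme="lin") -> VertexFunctional:
    """Sphere functional f_V(v) = sum_j c_j |S_j(v)|."""
    c, rho, sname = _resolve_scheme(g, scheme)
    d = distance_matrix(g)
    vals = np.empty(g.n)
    for v in range(g.n):
        row = d[v]
        k = np.bincount(row[row > 0], minlength=rho + 1)[1 : rho + 1]
        vals[v] = float(np.dot(c, k))
    return VertexFunctional("f_V", sname, np.log(vals), vals)


def functional_fP(g: Graph, scheme="lin") -> VertexFunctional:
    """Path functional f_P(v) = sum_j c_j sigma_j(v) over geodesic counts."""
    c, rho, sname = _resolve_scheme(g, scheme)
    d = distance_matrix(g)
    vals = np.empty(g.n)
    for v in range(g.n):
        sigma = _geodesic_counts(g, v, d)
        lev = np.zeros(rho + 1, dtype=np.int64)
        row = d[v]
        for u in range(g.n):
            if u != v:
                lev[row[u]] += sigma[u]
        vals[v] = float(np.dot(c, lev[1:]))
    return VertexFunctional("f_P", sname, np.log(vals), vals)


def frho_level_variations(g: Graph, v: int) -> np.ndarray:
    """lambda_j(v) for j = 1..rho: summed degree-sequence total variation.

    Every shortest path of length j starting at ``v`` contributes the total
    variation sum_i |deg(v_i) - deg(v_{i-1})| of the degrees along it.
    Returned as exact integers.
    """
    d = distance_matrix(g)
    rho = int(d.max())
    deg = g.degree()
    adj: list[list[int]] = [[] for _ in range(g.n)]
    for a, b in g.edges:
        adj[a].append(b)
        adj[b].append(a)
    lam = np.zeros(rho + 1, dtype=np.int64)
    row = d[v]
    # DFS over the geodesic DAG; tv accumulates the running total variation
    stack: list[tuple[int, int, int]] = [(v, 1, 0)]
    while stack:
        node, level, tv = stack.pop()
        for w in adj[node]:
            if row[w] == level:
                ntv = tv + abs(deg[node] - deg[w])
                lam[level] += ntv
                stack.append((w, level + 1, ntv))
    return lam[1:]


def functional_frho(
    g: Graph, scheme="lin", alpha: float = DEFAULT_FRHO_ALPHA
) -> VertexFunctional:
    """Degree-degree association functional f_rho(v) = alpha^(sum_j c_j lambda_j(v)).

    Well defined for every connected graph: on regular graphs all degree
    differences vanish and f_rho is identically alpha^0 = 1, so the entropy
    reaches its maximum log2 n.  Only ln f is materialised; the raw weights
    may be far outside double range for strongly heterogeneous graphs.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    c, rho, sname = _resolve_scheme(g, scheme)
    lna = math.log(alpha)
    logs = np.empty(g.n)
    for v in range(g.n):
        lam = frho_level_variations(g, v)
        logs[v] = lna * float(np.dot(c, lam))
    return VertexFunctional("f_rho", sname, logs, None)


def entropy_from_functional(fv: VertexFunctional) -> float:
    """Shannon entropy (bits) of the functional's vertex probabilities."""
    p = fv.probabilities()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_distance(fv: VertexFunctional, lam: float = 1.0) -> float:
    """Information distance lam * (log2 n - I_f); zero at maximum entropy."""
    if lam <= 0:
        raise ValueError("scaling constant must be positive")
    return lam * (math.log2(fv.n) - entropy_from_functional(fv))


def functional_frho_linear(g: Graph, scheme="lin") -> VertexFunctional:
    """Guarded linear composition f(v) = 1 + sum_j c_j lambda_j(v).

    A package extra alongside the canonical exponential composition: same
    degree-variation quantities, combined additively; the +1 keeps the
    functional positive on regular graphs.
    """
    c, rho, sname = _resolve_scheme(g, scheme)
    vals = np.empty(g.n)
    for v in range(g.n):
        lam = frho_level_variations(g, v)
        vals[v] = 1.0 + float(np.dot(c, lam))
    return VertexFunctional("f_rho_linear", sname, np.log(vals), vals)


def _make_index(func: Callable[..., VertexFunctional], scheme: str, **kw):
    def index(g: Graph) -> float:
        return entropy_from_functional(func(g, scheme, **kw))

    return index


#: Registry of the entropy-based indices.  ``ifrho_exp`` is the canonical
#: degree-degree association index: the *exponential composition* of the
#: linearly weighted degree variations (that composition is what the name's
#: "exp" refers to).  ``ifrho_lin``/``ifrho_quad`` are additive-composition
#: extras.
ENTROPY_INDICES: dict[str, Callable[[Graph], float]] = {
    "ifv_lin": _make_index(functional_fV, "lin"),
    "ifv_quad": _make_index(functional_fV, "quad"),
    "ifv_exp": _make_index(functional_fV, "exp"),
    "ifp_lin": _make_index(functional_fP, "lin"),
    "ifp_quad": _make_index(functional_fP, "quad"),
    "ifp_exp": _make_index(functional_fP, "exp"),
    "ifrho_lin": _make_index(functional_frho_linear, "lin"),
    "ifrho_quad": _make_index(functional_frho_linear, "quad"),
    "ifrho_exp": _make_index(functional_frho, "lin", alpha=DEFAULT_FRHO_ALPHA),
}
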