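"""Combined descriptor registry: classical indices plus entropy indices.

``DEFAULT_INDEX_SET`` lists the 27 canonical measures of the study (20
classical + I_fV and I_fP under three schemes each + the degree-degree
association index); the additive-composition f_rho variants are available
as extras.
"""

from __future__ import annotations

from typing import Callable

from .classical import CLASSICAL_INDICES
from .entropy import ENTROPY_INDICES
from .graph import Graph

__all__ = ["index_function", "available_indices", "DEFAULT_INDEX_SET"]

_CANONICAL_ENTROPY = (
    "ifv_lin", "ifv_quad", "ifv_exp",
    "ifp_lin", "ifp_quad", "ifp_exp",
    "ifrho_exp",
)

DEFAULT_INDEX_SET: tuple[str, ...] = tuple(CLASSICAL_INDICES) + _CANONICAL_ENTROPY


def available_indices() -> list[str]:
    return sorted(set(CLASSICAL_INDICES) | set(ENTROPY_INDICES))


def index_function(name: str) -> Callable[[Graph], float]:
    if name in CLASSICAL_INDICES:
        return CLASSICAL_INDICES[name].func
    if name in ENTROPY_INDICES:
        return ENTROPY_INDICES[name]
    raise KeyError(
        f"unknown index {name!r}; available: {', '.join(available_indices())}"
    )
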