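"""Spatial allocation of enzyme totals across grid regions.

Each enzyme's total cellular amount ``[E]`` is split over a scope of regions
K_E proportionally to non-negative weights ``n_k``::

    [E]_k = n_k / sum_{k in K_E} n_k * [E]

Four weight patterns are supported (figure-label mnemonics in quotes):

* ``uniform`` ("0") — n_k = 1 everywhere in scope;
* ``positive_gradient`` ("+") — n_k = 1 on the outermost layer, increasing
  by the gradient parameter per layer toward the cell centre;
* ``negative_gradient`` ("-") — the mirror image: n_k = 1 on the innermost
  layer in scope, increasing by the parameter magnitude per layer toward
  the boundary (so the boundary is richest);
* ``random`` ("r") — n_k drawn i.i.d. from Uniform(0, 1).

Transporters live on the membrane, so their scope is the boundary layer
only; cytosolic enzymes use the whole grid.  On a single-layer scope the
gradient patterns degenerate to uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_model import EnzymeSpec
from .grid import Grid

__all__ = [
    "DistributionPattern",
    "EnzymeAllocation",
    "allocate",
    "pattern_from_mnemonic",
    "MNEMONICS",
]

PATTERN_KINDS = ("uniform", "positive_gradient", "negative_gradient", "random")
SCOPES = ("all_regions", "boundary_only")

MNEMONICS = {
    "0": "uniform",
    "+": "positive_gradient",
    "-": "negative_gradient",
    "r": "random",
}


@dataclass(frozen=True)
class DistributionPattern:
    kind: str = "uniform"
    gradient_param: float = 1.0
    scope: str = "all_regions"

    def __post_init__(self):
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def mnemonic(self) -> str:
        return {v: k for k, v in MNEMONICS.items()}[self.kind]


def pattern_from_mnemonic(
    char: str, gradient_param: float = 1.0, scope: str = "all_regions"
) -> DistributionPattern:
    """Build a pattern from its one-character figure label (0/+/-/r)."""
    if char not in MNEMONICS:
        raise ValueError(f"unknown pattern mnemonic {char!r}; expected one of 0 + - r")
    return DistributionPattern(MNEMONICS[char], gradient_param, scope)


@dataclass
class EnzymeAllocation:
    """Per-region amounts of one enzyme; regions outside scope get zero."""

    enzyme_id: str
    amounts: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.amounts.values()))

    def amount(self, key: tuple[int, int]) -> float:
        return self.amounts.get(key, 0.0)


def _weights(pattern: DistributionPattern, scope_regions, rng) -> np.ndarray:
    layers = np.array([r.layer for r in scope_regions])
    g = abs(pattern.gradient_param)
    if pattern.kind == "uniform":
        return np.ones(len(scope_regions))
    if pattern.kind == "positive_gradient":
        return 1.0 + g * (layers - layers.min())
    if pattern.kind == "negative_gradient":
        return 1.0 + g * (layers.max() - layers)
    # random
    if rng is None:
        raise ValueError("random allocation requires a seeded random generator")
    w = rng.uniform(0.0, 1.0, size=len(scope_regions))
    while w.sum() == 0.0:  # probability-zero guard
        w = rng.uniform(0.0, 1.0, size=len(scope_regions))
    return w


def allocate(
    enzyme: EnzymeSpec,
    pattern: DistributionPattern,
    grid: Grid,
    rng: np.random.Generator | None = None,
) -> EnzymeAllocation:
    """Split ``enzyme.total_amount`` over the pattern's scope on ``grid``."""
    if pattern.scope == "boundary_only":
        scope = grid.boundary_regions()
    else:
        scope = list(grid.regions)
    if not scope:
        raise ValueError("allocation scope is empty")
    w = _weights(pattern, scope, rng)
    portions = w / w.sum() * enzyme.total_amount
    return EnzymeAllocation(
        enzyme.id, {r.key: float(p) for r, p in zip(scope, portions)}
    )
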