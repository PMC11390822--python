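"""Expansion of a cell-scale model onto a grid: the discretised LP.

The discretiser turns a :class:`~gridfba.cell_model.CellScaleModel` plus a
:class:`~gridfba.grid.Grid`, per-enzyme spatial allocations and a diffusion
policy into a single :class:`RegionalModel` linear program:

1. every *cellular* metabolite is decomposed into one regional species per
   grid region; extracellular species stay singular (the medium is one
   homogeneous compartment outside the grid);
2. every intracellular (and pseudo-sink) reaction is replicated per region;
   catalysed copies are capacity-bounded by ``kcat * [E]_k`` using the
   region's allocated enzyme portion;
3. every cross-membrane transport reaction is replicated once per *boundary*
   region, drawing on the shared extracellular pool;
4. exchange reactions touching only extracellular species stay whole-cell;
5. for each cellular metabolite whose policy allows diffusion, a pair of
   opposed directed flux variables (lower bound 0) is created per
   4-connected neighbour pair, with stoichiometry -1 at the source region
   and +1 at the target;
6. the objective is recomposed: a cell-scale weight w on reaction r becomes
   weight w on every regional copy, so the optimum reports the whole-cell
   total.

Metabolites with policy ``none`` simply get no diffusion variables — the
diffusion-limited regime — which keeps the LP small and is equivalent to
pinning those fluxes at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .allocation import EnzymeAllocation
from .cell_model import CELLULAR, EXTRACELLULAR, CellScaleModel, validate_model
from .grid import Grid

__all__ = ["DiffusionPolicy", "Provenance", "RegionalModel", "discretise", "diffusion_edges"]

INSTANTANEOUS = "instantaneous"
NONE = "none"


@dataclass(frozen=True)
class DiffusionPolicy:
    """Per-metabolite diffusion setting.

    ``settings`` maps a cellular metabolite id to ``"instantaneous"``
    (diffusion variables with unbounded rate), ``"none"`` (no diffusion
    variables at all), or a finite non-negative per-edge flux cap.
    Metabolites absent from the map default to ``"none"``.
    """

    settings: dict[str, object] = field(default_factory=dict)

    def setting(self, met_id: str):
        return self.settings.get(met_id, NONE)

    def diffusible(self, met_id: str) -> bool:
        s = self.setting(met_id)
        return s != NONE

    def edge_upper_bound(self, met_id: str) -> float:
        s = self.setting(met_id)
        if s == INSTANTANEOUS:
            return math.inf
        if s == NONE:
            return 0.0
        u = float(s)
        if u < 0:
            raise ValueError(f"diffusion bound for {met_id!r} must be non-negative")
        return u

    @classmethod
    def instantaneous_for(cls, metabolite_ids) -> "DiffusionPolicy":
        return cls({m: INSTANTANEOUS for m in metabolite_ids})

    @classmethod
    def no_diffusion(cls) -> "DiffusionPolicy":
        return cls({})


@dataclass(frozen=True)
class Provenance:
    """Where a regional LP variable came from.

    ``kind`` is ``"reaction"`` (cell-scale reaction id, region key or None
    for whole-cell reactions) or ``"diffusion"`` (metabolite id, source and
    target region keys).
    """

    kind: str
    ref: str
    region: tuple[int, int] | None = None
    target: tuple[int, int] | None = None


@dataclass
class RegionalModel:
    """The expanded LP: maximise c.v subject to S v = 0, l <= v <= u."""

    name: str
    variables: list[str]
    metabolite_rows: list[str]
    S: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    provenance: list[Provenance]
    grid: Grid
    source: CellScaleModel

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_rows)

    def variable_index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise KeyError(f"no variable {name!r}") from None

    def indices_for_reaction(self, rxn_id: str) -> list[int]:
        """Column indices of every regional copy of a cell-scale reaction."""
        return [
            i
            for i, p in enumerate(self.provenance)
            if p.kind == "reaction" and p.ref == rxn_id
        ]

    def to_lp_string(self) -> str:
        """CPLEX LP-format text of the problem, for solver-independent debugging."""
        def num(x):
            return f"{x:.12g}"

        lines = ["Maximize", " obj:"]
        terms = [
            f" {'+' if w >= 0 else '-'} {num(abs(w))} {v}"
            for v, w in zip(self.variables, self.objective)
            if w != 0
        ]
        lines[-1] += "".join(terms) if terms else " 0 x0"
        lines.append("Subject To")
        Scsc = self.S.tocoo()
        rows: dict[int, list[str]] = {}
        for i, j, val in zip(Scsc.row, Scsc.col, Scsc.data):
            rows.setdefault(i, []).append(
                f" {'+' if val >= 0 else '-'} {num(abs(val))} {self.variables[j]}"
            )
        for i, met in enumerate(self.metabolite_rows):
            body = "".join(rows.get(i, [" + 0 " + self.variables[0]]))
            lines.append(f" m{i}:{body} = 0")
        lines.append("Bounds")
        for v, lo, hi in zip(self.variables, self.lower, self.upper):
            lo_s = "-inf" if lo == -math.inf else num(lo)
            hi_s = "+inf" if hi == math.inf else num(hi)
            lines.append(f" {lo_s} <= {v} <= {hi_s}")
        lines.append("End")
        return "\n".join(lines) + "\n"

    def write_lp(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_lp_string())


def _region_species(met_id: str, key: tuple[int, int]) -> str:
    return f"{met_id}@{key[0]},{key[1]}"


def diffusion_edges(grid: Grid, metabolite_id: str, policy: DiffusionPolicy):
    """Directed diffusion edge descriptors (name, src, dst, upper bound).

    Empty when the metabolite's policy is ``none``; otherwise two opposed
    edges per 4-connected neighbour pair.
    """
    if not policy.diffusible(metabolite_id):
        return []
    ub = policy.edge_upper_bound(metabolite_id)
    edges = []
    for a, b in grid.neighbour_pairs:
        for src, dst in ((a, b), (b, a)):
            name = f"D[{metabolite_id}]@{src[0]},{src[1]}->{dst[0]},{dst[1]}"
            edges.append((name, src, dst, ub))
    return edges


def discretise(
    model: CellScaleModel,
    grid: Grid,
    allocations: dict[str, EnzymeAllocation],
    policy: DiffusionPolicy,
) -> RegionalModel:
    """Expand ``model`` onto ``grid`` into a single regional LP.

    ``allocations`` maps enzyme id to its spatial allocation; every
    catalysed reaction's enzyme must be covered.  Raises ``ValueError`` on
    a structurally invalid model, a missing allocation, or an allocation
    that references regions outside the grid.
    """
    problems = validate_model(model)
    if problems:
        raise ValueError(
            "cannot discretise an invalid model: " + "; ".join(problems)
        )
    for rxn in model.reactions:
        if rxn.catalyst is not None and rxn.kind != "exchange":
            if rxn.catalyst not in allocations:
                raise ValueError(
                    f"reaction {rxn.id!r} is catalysed by {rxn.catalyst!r} "
                    "but no allocation was provided for that enzyme"
                )
    valid_keys = {r.key for r in grid.regions}
    for alloc in allocations.values():
        extra = set(alloc.amounts) - valid_keys
        if extra:
            raise ValueError(
                f"allocation for {alloc.enzyme_id!r} references regions outside "
                f"the {grid.rows}x{grid.cols} grid: {sorted(extra)}"
            )
    for met_id in policy.settings:
        if model.metabolite(met_id).compartment != CELLULAR:
            raise ValueError(
                f"diffusion policy applies only to cellular metabolites, got {met_id!r}"
            )

    cellular = {m.id for m in model.cellular_metabolites()}

    # Rows: extracellular species singular, cellular species one per region.
    metabolite_rows: list[str] = []
    row_of: dict[str, int] = {}
    for m in model.metabolites:
        if m.compartment == EXTRACELLULAR:
            row_of[m.id] = len(metabolite_rows)
            metabolite_rows.append(m.id)
        else:
            for region in grid.regions:
                name = _region_species(m.id, region.key)
                row_of[name] = len(metabolite_rows)
                metabolite_rows.append(name)

    variables: list[str] = []
    provenance: list[Provenance] = []
    lower: list[float] = []
    upper: list[float] = []
    objective: list[float] = []
    entries: list[tuple[int, int, float]] = []  # (row, col, coeff)

    def add_variable(name, prov, lo, hi, weight, stoich_rows):
        col = len(variables)
        variables.append(name)
        provenance.append(prov)
        lower.append(lo)
        upper.append(hi)
        objective.append(weight)
        for row, coeff in stoich_rows:
            entries.append((row, col, coeff))

    def regional_stoich(rxn, key):
        rows = []
        for met, coeff in rxn.stoichiometry.items():
            if met in cellular:
                rows.append((row_of[_region_species(met, key)], coeff))
            else:
                rows.append((row_of[met], coeff))
        return rows

    for rxn in model.reactions:
        touches_cellular = any(m in cellular for m in rxn.stoichiometry)
        if rxn.kind == "exchange" or not touches_cellular:
            # whole-cell reaction: original bounds, original weight
            add_variable(
                rxn.id,
                Provenance("reaction", rxn.id),
                rxn.lower_bound,
                rxn.upper_bound,
                rxn.objective_weight,
                [(row_of[m], c) for m, c in rxn.stoichiometry.items()],
            )
            continue
        if rxn.kind == "transport":
            targets = grid.boundary_regions()
        else:
            targets = list(grid.regions)
        for region in targets:
            lo, hi = rxn.lower_bound, rxn.upper_bound
            if rxn.catalyst is not None:
                enz = model.enzyme(rxn.catalyst)
                hi = min(hi, enz.kcat * allocations[rxn.catalyst].amount(region.key))
                lo = max(lo, 0.0)
            add_variable(
                f"{rxn.id}@{region.row},{region.col}",
                Provenance("reaction", rxn.id, region.key),
                lo,
                hi,
                rxn.objective_weight,
                regional_stoich(rxn, region.key),
            )

    for m in model.metabolites:
        if m.compartment != CELLULAR:
            continue
        for name, src, dst, ub in diffusion_edges(grid, m.id, policy):
            add_variable(
                name,
                Provenance("diffusion", m.id, src, dst),
                0.0,
                ub,
                0.0,
                [
                    (row_of[_region_species(m.id, src)], -1.0),
                    (row_of[_region_species(m.id, dst)], 1.0),
                ],
            )

    rows_idx = [e[0] for e in entries]
    cols_idx = [e[1] for e in entries]
    data = [e[2] for e in entries]
    S = sparse.csr_matrix(
        (data, (rows_idx, cols_idx)),
        shape=(len(metabolite_rows), len(variables)),
    )
    return RegionalModel(
        name=f"{model.name}@{grid.rows}x{grid.cols}",
        variables=variables,
        metabolite_rows=metabolite_rows,
        S=S,
        lower=np.array(lower),
        upper=np.array(upper),
        objective=np.array(objective),
        provenance=provenance,
        grid=grid,
        source=model,
    )
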