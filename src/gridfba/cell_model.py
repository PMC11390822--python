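"""Cell-scale constraint-based metabolic models.

A :class:`CellScaleModel` is the conventional-FBA view of a cell: a set of
metabolites (each living in the extracellular compartment ``"e"`` or the
cellular compartment ``"c"``), a set of reactions with signed stoichiometry
(substrates negative, products positive), flux bounds, objective weights and
optional catalyst annotations, and a set of enzymes/transporters with a total
cellular amount and a turnover number ``kcat``.  A reaction catalysed by
enzyme E is capacity-bounded by ``kcat_E * [E]``.

Two toy pathways ship as builders:

* :func:`build_linear_model` — nutrient uptake followed by a two-step linear
  conversion to biomass (reactions R1-R5, enzymes E1-E3),
* :func:`build_branched_model` — a branch point where an intermediate Y can
  yield energy efficiently (R9, 4 units) or quickly but with a toxic
  by-product (R10, 3 units + toxin); the objective is the linearly scalarised
  pair *maximise energy, penalise toxin* with weights (+1, -2).

Units are abstract but mutually consistent: fluxes are particles per unit
time per cell, enzyme amounts particles per cell, kcat per unit time.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "EXTRACELLULAR",
    "CELLULAR",
    "MetaboliteSpec",
    "ReactionSpec",
    "EnzymeSpec",
    "CellScaleModel",
    "build_linear_model",
    "build_branched_model",
    "apply_variant",
    "validate_model",
    "model_from_dict",
    "load_model",
    "save_model",
    "read_sbml",
    "BUILTIN_MODELS",
]

EXTRACELLULAR = "e"
CELLULAR = "c"

REACTION_KINDS = ("exchange", "transport", "intracellular", "pseudo")
VARIANTS = ("default", "B_limiting", "A_limiting")


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite species in one compartment (``"e"`` or ``"c"``)."""

    id: str
    compartment: str = CELLULAR


@dataclass
class ReactionSpec:
    """A reaction column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative for substrates, positive for products).  ``kind`` controls how
    the spatial discretiser treats the reaction: ``exchange`` reactions touch
    only extracellular species and stay whole-cell, ``transport`` reactions
    cross the plasma membrane and are replicated per boundary region,
    ``intracellular`` reactions are replicated in every region, and
    ``pseudo`` sinks (biomass/energy/toxin drains) are replicated in every
    region with lower bound zero.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    objective_weight: float = 0.0
    catalyst: str | None = None
    kind: str = "intracellular"


@dataclass(frozen=True)
class EnzymeSpec:
    """An enzyme or transporter: total cellular amount and turnover number."""

    id: str
    total_amount: float = 100.0
    kcat: float = 1.0


@dataclass
class CellScaleModel:
    name: str
    metabolites: list[MetaboliteSpec] = field(default_factory=list)
    reactions: list[ReactionSpec] = field(default_factory=list)
    enzymes: list[EnzymeSpec] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.name!r}")

    def reaction(self, rxn_id: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.name!r}")

    def enzyme(self, enz_id: str) -> EnzymeSpec:
        for e in self.enzymes:
            if e.id == enz_id:
                return e
        raise KeyError(f"no enzyme {enz_id!r} in model {self.name!r}")

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def cellular_metabolites(self) -> list[MetaboliteSpec]:
        return [m for m in self.metabolites if m.compartment == CELLULAR]

    def stoichiometric_matrix(self):
        """Dense S matrix (metabolites x reactions), row/column order as declared."""
        import numpy as np

        row = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                S[row[met], j] = coeff
        return S

    def capacity_bounds(self, rxn: ReactionSpec) -> tuple[float, float]:
        """Effective cell-scale bounds, applying the kcat*[E] capacity cap."""
        lo, hi = rxn.lower_bound, rxn.upper_bound
        if rxn.catalyst is not None:
            enz = self.enzyme(rxn.catalyst)
            hi = min(hi, enz.kcat * enz.total_amount)
        return lo, hi

    def objective_vector(self):
        import numpy as np

        return np.array([r.objective_weight for r in self.reactions])

    def copy(self) -> "CellScaleModel":
        return copy.deepcopy(self)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metabolites": [
                {"id": m.id, "compartment": m.compartment} for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": dict(r.stoichiometry),
                    "lower_bound": _num_out(r.lower_bound),
                    "upper_bound": _num_out(r.upper_bound),
                    "objective_weight": r.objective_weight,
                    "catalyst": r.catalyst,
                    "kind": r.kind,
                }
                for r in self.reactions
            ],
            "enzymes": [
                {"id": e.id, "total_amount": e.total_amount, "kcat": e.kcat}
                for e in self.enzymes
            ],
        }


def _num_out(x: float):
    if x == math.inf:
        return "inf"
    if x == -math.inf:
        return "-inf"
    return x


def _num_in(x) -> float:
    if isinstance(x, str):
        return float(x)
    return float(x)


def model_from_dict(d: dict) -> CellScaleModel:
    return CellScaleModel(
        name=d["name"],
        metabolites=[
            MetaboliteSpec(m["id"], m.get("compartment", CELLULAR))
            for m in d["metabolites"]
        ],
        reactions=[
            ReactionSpec(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=_num_in(r.get("lower_bound", 0.0)),
                upper_bound=_num_in(r.get("upper_bound", "inf")),
                objective_weight=float(r.get("objective_weight", 0.0)),
                catalyst=r.get("catalyst"),
                kind=r.get("kind", "intracellular"),
            )
            for r in d["reactions"]
        ],
        enzymes=[
            EnzymeSpec(e["id"], float(e.get("total_amount", 100.0)), float(e.get("kcat", 1.0)))
            for e in d.get("enzymes", [])
        ],
    )


def save_model(model: CellScaleModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def load_model(path) -> CellScaleModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Built-in toy pathways
# ---------------------------------------------------------------------------

def build_linear_model() -> CellScaleModel:
    """Linear pathway: uptake of A, conversion A -> B -> Biomass.

    Reactions::

        R1:          -> A[e]          (exchange, nutrient source, ub 100)
        R2:  A[e]    -> A[c]   via E1 (transport)
        R3:  A[c]    -> B[c]   via E2
        R4:  B[c]    -> Biomass via E3
        R5:  Biomass ->               (biomass sink, the objective)

    All reactions irreversible; enzyme totals 100, kcat 1.0; the parameter
    set makes the cell-scale optimum exactly 100 with no single enzyme
    limiting.
    """
    return CellScaleModel(
        name="linear",
        metabolites=[
            MetaboliteSpec("A[e]", EXTRACELLULAR),
            MetaboliteSpec("A[c]", CELLULAR),
            MetaboliteSpec("B[c]", CELLULAR),
            MetaboliteSpec("Biomass", CELLULAR),
        ],
        reactions=[
            ReactionSpec("R1", {"A[e]": 1.0}, 0.0, 100.0, kind="exchange"),
            ReactionSpec("R2", {"A[e]": -1.0, "A[c]": 1.0}, catalyst="E1", kind="transport"),
            ReactionSpec("R3", {"A[c]": -1.0, "B[c]": 1.0}, catalyst="E2"),
            ReactionSpec("R4", {"B[c]": -1.0, "Biomass": 1.0}, catalyst="E3"),
            ReactionSpec("R5", {"Biomass": -1.0}, objective_weight=1.0, kind="pseudo"),
        ],
        enzymes=[EnzymeSpec("E1"), EnzymeSpec("E2"), EnzymeSpec("E3")],
    )


def build_branched_model() -> CellScaleModel:
    """Branched pathway: X -> Y, then Y -> energy via two competing routes.

    Reactions::

        R6:           -> X[e]                (exchange, ub 100)
        R7:  X[e]     -> X[c]         via E4 (transport)
        R8:  X[c]     -> Y[c]         via E5
        R9:  Y[c]     -> 4 Energy     via E6 (primary path)
        R10: Y[c]     -> 3 Energy + Toxin  via E7 (secondary path, kcat 2)
        R11: Energy   ->                     (sink, weight +1)
        R12: Toxin    ->                     (sink, weight -2)

    The scalarised objective Z = v_R11 - 2 v_R12 rewards energy and strongly
    penalises toxin, so the secondary path is used only when spatial
    constraints leave primary capacity stranded.
    """
    return CellScaleModel(
        name="branched",
        metabolites=[
            MetaboliteSpec("X[e]", EXTRACELLULAR),
            MetaboliteSpec("X[c]", CELLULAR),
            MetaboliteSpec("Y[c]", CELLULAR),
            MetaboliteSpec("Energy", CELLULAR),
            MetaboliteSpec("Toxin", CELLULAR),
        ],
        reactions=[
            ReactionSpec("R6", {"X[e]": 1.0}, 0.0, 100.0, kind="exchange"),
            ReactionSpec("R7", {"X[e]": -1.0, "X[c]": 1.0}, catalyst="E4", kind="transport"),
            ReactionSpec("R8", {"X[c]": -1.0, "Y[c]": 1.0}, catalyst="E5"),
            ReactionSpec("R9", {"Y[c]": -1.0, "Energy": 4.0}, catalyst="E6"),
            ReactionSpec("R10", {"Y[c]": -1.0, "Energy": 3.0, "Toxin": 1.0}, catalyst="E7"),
            ReactionSpec("R11", {"Energy": -1.0}, objective_weight=1.0, kind="pseudo"),
            ReactionSpec("R12", {"Toxin": -1.0}, objective_weight=-2.0, kind="pseudo"),
        ],
        enzymes=[
            EnzymeSpec("E4"),
            EnzymeSpec("E5"),
            EnzymeSpec("E6"),
            EnzymeSpec("E7", kcat=2.0),
        ],
    )


BUILTIN_MODELS = {"linear": build_linear_model, "branched": build_branched_model}


def apply_variant(model: CellScaleModel, variant: str) -> CellScaleModel:
    """Stoichiometric variants of the linear pathway.

    ``B_limiting`` makes the biomass step consume 2 B per unit
    (2 B[c] -> Biomass), so E3 is in excess at the cell scale;
    ``A_limiting`` makes the A->B step consume 2 A per unit
    (2 A[c] -> B[c]), so both E2 and E3 are in excess.  Enzyme totals are
    untouched so allocation patterns remain comparable across variants.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "default":
        return model
    out = model.copy()
    try:
        if variant == "B_limiting":
            rxn = out.reaction("R4")
            rxn.stoichiometry["B[c]"] = -2.0
        else:  # A_limiting
            rxn = out.reaction("R3")
            rxn.stoichiometry["A[c]"] = -2.0
    except KeyError as exc:
        raise ValueError(
            f"variant {variant!r} requires the linear-pathway reactions R3/R4"
        ) from exc
    out.name = f"{model.name}:{variant}"
    return out


def validate_model(model: CellScaleModel) -> list[str]:
    """Structural diagnostics; an empty list means the model is well formed."""
    problems: list[str] = []
    met_ids = model.metabolite_ids
    seen = set()
    for mid in met_ids:
        if mid in seen:
            problems.append(f"duplicate metabolite id {mid!r}")
        seen.add(mid)
    for m in model.metabolites:
        if m.compartment not in (EXTRACELLULAR, CELLULAR):
            problems.append(
                f"metabolite {m.id!r}: unknown compartment {m.compartment!r}"
            )
    enz_ids = {e.id for e in model.enzymes}
    rxn_seen = set()
    for r in model.reactions:
        if r.id in rxn_seen:
            problems.append(f"duplicate reaction id {r.id!r}")
        rxn_seen.add(r.id)
        for met in r.stoichiometry:
            if met not in seen:
                problems.append(
                    f"reaction {r.id!r}: stoichiometry references undeclared metabolite {met!r}"
                )
        if r.lower_bound > r.upper_bound:
            problems.append(
                f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds upper bound {r.upper_bound}"
            )
        if r.catalyst is not None and r.catalyst not in enz_ids:
            problems.append(
                f"reaction {r.id!r}: catalyst {r.catalyst!r} is not a declared enzyme"
            )
        if r.kind not in REACTION_KINDS:
            problems.append(f"reaction {r.id!r}: unknown kind {r.kind!r}")
        if r.kind == "transport":
            comps = {
                model.metabolite(m).compartment
                for m in r.stoichiometry
                if m in seen
            }
            if not {EXTRACELLULAR, CELLULAR} <= comps:
                problems.append(
                    f"transport reaction {r.id!r} must span both compartments"
                )
    for e in model.enzymes:
        if e.total_amount < 0:
            problems.append(f"enzyme {e.id!r}: negative total amount")
        if e.kcat <= 0:
            problems.append(f"enzyme {e.id!r}: kcat must be positive")
    if not any(r.objective_weight != 0 for r in model.reactions):
        problems.append("no reaction carries a nonzero objective weight")
    return problems


def read_sbml(path, catalysts: dict[str, str] | None = None,
              enzymes: list[EnzymeSpec] | None = None) -> CellScaleModel:
    """Import a cell-scale model from an SBML Level 3 + FBC document.

    Species map to metabolites (compartment ids other than ``"e"`` are
    treated as cellular), reactions carry FBC flux bounds and objective
    coefficients.  SBML has no standard slot for catalyst/kcat annotations,
    so ``catalysts`` (reaction id -> enzyme id) and ``enzymes`` are supplied
    separately when capacity constraints are wanted.
    """
    import libsbml

    def strip(sid: str, prefix: str) -> str:
        # cobra-style SBML ids carry M_/R_ prefixes; drop them on import
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"SBML parse error in {path}")
    sbml_model = doc.getModel()
    fbc = sbml_model.getPlugin("fbc")
    catalysts = catalysts or {}

    def param_value(pid):
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else None

    objective_coeffs: dict[str, float] = {}
    if fbc is not None and fbc.getActiveObjective() is not None:
        for i in range(fbc.getActiveObjective().getNumFluxObjectives()):
            fo = fbc.getActiveObjective().getFluxObjective(i)
            objective_coeffs[strip(fo.getReaction(), "R_")] = fo.getCoefficient()

    mets = []
    compartment_of = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        comp = EXTRACELLULAR if sp.getCompartment() == "e" else CELLULAR
        sid = strip(sp.getId(), "M_")
        compartment_of[sid] = comp
        mets.append(MetaboliteSpec(sid, comp))

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            sid = strip(sr.getSpecies(), "M_")
            stoich[sid] = stoich.get(sid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            sid = strip(sr.getSpecies(), "M_")
            stoich[sid] = stoich.get(sid, 0.0) + sr.getStoichiometry()
        lo, hi = 0.0, math.inf
        plug = rx.getPlugin("fbc")
        if plug is not None:
            v = param_value(plug.getLowerFluxBound())
            if v is not None:
                lo = v
            v = param_value(plug.getUpperFluxBound())
            if v is not None:
                hi = v
        comps = {compartment_of[m] for m in stoich}
        if comps == {EXTRACELLULAR}:
            kind = "exchange"
        elif comps == {EXTRACELLULAR, CELLULAR}:
            kind = "transport"
        else:
            kind = "intracellular"
        rid = strip(rx.getId(), "R_")
        rxns.append(
            ReactionSpec(
                rid, stoich, lo, hi,
                objective_weight=objective_coeffs.get(rid, 0.0),
                catalyst=catalysts.get(rid),
                kind=kind,
            )
        )
    return CellScaleModel(
        name=sbml_model.getId() or "sbml_model",
        metabolites=mets,
        reactions=rxns,
        enzymes=list(enzymes or []),
    )
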