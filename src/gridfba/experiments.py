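"""The simulation battery: shape sweeps, diffusion regimes, pattern sweeps
and stochastic batches.

A :class:`RunConfig` names a built-in model (and optional stoichiometric
variant), a grid shape, the set of metabolites allowed to diffuse
(instantaneously), and one distribution-pattern mnemonic per enzyme in
declaration order — e.g. ``"0+-"`` puts transporter E1 uniform on the
boundary, E2 on a positive gradient and E3 on a negative one.  Transporters
(enzymes facilitating a transport reaction) are always confined to the
boundary layer.

Deterministic sweeps cross shapes x regimes x pattern combinations;
stochastic batches redraw the random allocations each replicate and report
mean, standard deviation and the coefficient of variation CV = std/mean
(sample standard deviation, n-1 denominator), the population-variability
measure used throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .allocation import DistributionPattern, allocate, pattern_from_mnemonic
from .cell_model import BUILTIN_MODELS, CellScaleModel, apply_variant
from .discretiser import DiffusionPolicy, discretise
from .grid import PAPER_SHAPES, build_grid, pa_ratio
from .lp_core import solve

__all__ = [
    "RunConfig",
    "RunResult",
    "BatchStats",
    "regime_metabolites",
    "REGIMES",
    "run_single",
    "run_deterministic_sweep",
    "run_stochastic_batch",
    "compute_cv",
    "secondary_primary_ratio",
    "pattern_combinations",
]

#: Diffusion regimes per built-in model: regime name -> diffusible metabolites.
REGIMES = {
    "linear": {
        "none": (),
        "A": ("A[c]",),
        "B": ("B[c]",),
        "both": ("A[c]", "B[c]"),
    },
    "branched": {
        "none": (),
        "X": ("X[c]",),
        "Y": ("Y[c]",),
        "both": ("X[c]", "Y[c]"),
    },
}


def regime_metabolites(model_name: str, regime: str) -> tuple[str, ...]:
    base = model_name.split(":")[0]
    try:
        return REGIMES[base][regime]
    except KeyError:
        raise ValueError(
            f"unknown regime {regime!r} for model {model_name!r}; "
            f"expected one of {sorted(REGIMES.get(base, {}))}"
        ) from None


@dataclass(frozen=True)
class RunConfig:
    model: str = "linear"
    variant: str = "default"
    rows: int = 6
    cols: int = 6
    diffusible: tuple[str, ...] = ("A[c]", "B[c]")
    patterns: str = "000"            # one mnemonic per enzyme, declaration order
    gradient_param: float = 1.0
    seed: int | None = None

    @property
    def regime_label(self) -> str:
        base = self.model.split(":")[0]
        for name, mets in REGIMES.get(base, {}).items():
            if tuple(sorted(mets)) == tuple(sorted(self.diffusible)):
                return name
        return "+".join(self.diffusible) if self.diffusible else "none"

    @property
    def is_stochastic(self) -> bool:
        return "r" in self.patterns

    def with_regime(self, regime: str) -> "RunConfig":
        return replace(self, diffusible=regime_metabolites(self.model, regime))


@dataclass
class RunResult:
    """Aggregated outcome of one LP solve.

    ``totals`` sums the regional copies of each cell-scale reaction, which
    is invariant across degenerate alternate optima of the per-region split
    whenever the objective is; named accessors expose the quantities the
    analyses use.
    """

    status: str
    objective_value: float | None
    totals: dict[str, float]
    pa_ratio: float
    n_variables: int
    config: RunConfig

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def total(self, rxn_id: str) -> float:
        return self.totals.get(rxn_id, 0.0)

    @property
    def growth(self) -> float:
        return self.total("R5")

    @property
    def energy(self) -> float:
        return self.total("R11")

    @property
    def toxin(self) -> float:
        return self.total("R12")

    @property
    def primary_flux(self) -> float:
        return self.total("R9")

    @property
    def secondary_flux(self) -> float:
        return self.total("R10")


@dataclass(frozen=True)
class BatchStats:
    n: int
    mean: float
    std: float
    cv: float


def _resolve_model(config: RunConfig) -> CellScaleModel:
    try:
        model = BUILTIN_MODELS[config.model]()
    except KeyError:
        raise ValueError(
            f"unknown model {config.model!r}; expected one of {sorted(BUILTIN_MODELS)}"
        ) from None
    return apply_variant(model, config.variant)


def _build_patterns(model: CellScaleModel, config: RunConfig) -> dict[str, DistributionPattern]:
    if len(config.patterns) != len(model.enzymes):
        raise ValueError(
            f"pattern string {config.patterns!r} has {len(config.patterns)} characters "
            f"but model {model.name!r} declares {len(model.enzymes)} enzymes"
        )
    transporters = {
        r.catalyst for r in model.reactions if r.kind == "transport" and r.catalyst
    }
    out = {}
    for enz, char in zip(model.enzymes, config.patterns):
        scope = "boundary_only" if enz.id in transporters else "all_regions"
        out[enz.id] = pattern_from_mnemonic(char, config.gradient_param, scope)
    return out


def run_single(config: RunConfig, rng: np.random.Generator | None = None) -> RunResult:
    """Build, discretise and solve one configuration.

    Random patterns draw from ``rng`` (created from ``config.seed`` when not
    supplied).  An infeasible or unbounded LP is reported in the result
    status rather than raised.
    """
    if config.is_stochastic and rng is None:
        if config.seed is None:
            raise ValueError("a seed (or generator) is required for random patterns")
        rng = np.random.default_rng(config.seed)
    model = _resolve_model(config)
    grid = build_grid(config.rows, config.cols)
    patterns = _build_patterns(model, config)
    allocations = {
        enz.id: allocate(enz, patterns[enz.id], grid, rng) for enz in model.enzymes
    }
    policy = DiffusionPolicy.instantaneous_for(config.diffusible)
    regional = discretise(model, grid, allocations, policy)
    sol = solve(regional)
    totals = {}
    if sol.optimal:
        for rxn in model.reactions:
            idx = regional.indices_for_reaction(rxn.id)
            totals[rxn.id] = float(
                sum(sol.fluxes[regional.variables[i]] for i in idx)
            )
    return RunResult(
        status=sol.status,
        objective_value=sol.objective_value,
        totals=totals,
        pa_ratio=pa_ratio(grid),
        n_variables=regional.n_variables,
        config=config,
    )


def pattern_combinations(n_slots: int, chars: str = "0+-"):
    """All deterministic pattern strings for ``n_slots`` enzymes."""
    return ["".join(c) for c in itertools.product(chars, repeat=n_slots)]


def run_deterministic_sweep(
    model: str = "linear",
    variant: str = "default",
    shapes=PAPER_SHAPES,
    regimes=("none", "both"),
    patterns=("000",),
    gradient_param: float = 1.0,
) -> pd.DataFrame:
    """Cross shapes x regimes x pattern strings; one row per run.

    Only deterministic patterns are allowed — use
    :func:`run_stochastic_batch` for random ones.
    """
    rows = []
    for (I, J), regime, pat in itertools.product(shapes, regimes, patterns):
        if "r" in pat:
            raise ValueError("deterministic sweep cannot include random patterns")
        config = RunConfig(
            model=model,
            variant=variant,
            rows=I,
            cols=J,
            diffusible=regime_metabolites(model, regime),
            patterns=pat,
            gradient_param=gradient_param,
        )
        result = run_single(config)
        rows.append(
            {
                "rows": I,
                "cols": J,
                "pa_ratio": result.pa_ratio,
                "regime": regime,
                "patterns": pat,
                "status": result.status,
                "objective": result.objective_value,
                "growth": result.growth,
                "energy": result.energy,
                "toxin": result.toxin,
                "primary_flux": result.primary_flux,
                "secondary_flux": result.secondary_flux,
            }
        )
    return pd.DataFrame(rows)


def compute_cv(values) -> float:
    """Coefficient of variation: sample std (ddof=1) over mean; 0 for constant lists."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least two values")
    std = float(np.std(arr, ddof=1))
    if std == 0.0:
        return 0.0
    mean = float(np.mean(arr))
    if mean == 0.0:
        raise ValueError("CV is undefined: zero mean with nonzero spread")
    return std / mean


def run_stochastic_batch(
    config: RunConfig, n: int = 100, seed: int | None = None
) -> tuple[dict[str, BatchStats], pd.DataFrame]:
    """Run ``n`` replicates, redrawing every random allocation each time.

    Returns per-quantity :class:`BatchStats` (objective plus growth or
    energy/toxin depending on the model) and the per-replicate table.
    Infeasible replicates are excluded from the statistics and counted in
    the table's ``status`` column.
    """
    if n < 2:
        raise ValueError("a batch needs at least two replicates")
    if not config.is_stochastic:
        raise ValueError("stochastic batch requires at least one random pattern")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    for rep in range(n):
        result = run_single(config, rng=rng)
        records.append(
            {
                "replicate": rep,
                "status": result.status,
                "objective": result.objective_value,
                "growth": result.growth,
                "energy": result.energy,
                "toxin": result.toxin,
                "primary_flux": result.primary_flux,
                "secondary_flux": result.secondary_flux,
            }
        )
    table = pd.DataFrame(records)
    ok = table[table["status"] == "optimal"]
    quantities = ["objective"]
    quantities.append("growth" if config.model.startswith("linear") else "energy")
    stats = {}
    for q in quantities:
        vals = ok[q].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        std = float(np.std(vals, ddof=1))
        cv = 0.0 if std == 0.0 else (math.inf if mean == 0.0 else std / mean)
        stats[q] = BatchStats(n=len(vals), mean=mean, std=std, cv=cv)
    return stats, table


def secondary_primary_ratio(result: RunResult) -> float:
    """Summed secondary-path flux (R10) over summed primary-path flux (R9)."""
    primary = result.primary_flux
    secondary = result.secondary_flux
    if primary == 0.0:
        return 0.0 if abs(secondary) < 1e-9 else math.inf
    return secondary / primary
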