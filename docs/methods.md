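# Methods

## The model

`gridfba` treats a cell as an *I* × *J* rectangle of unit square regions
and the extracellular medium as a single homogeneous compartment outside
the grid. A cell-scale constraint-based model — metabolites with a
compartment tag, irreversible-by-default reactions with signed
stoichiometry, flux bounds, objective weights and optional catalyst
annotations — is expanded into one regional linear program:

1. every cellular metabolite becomes one species per region; extracellular
   species stay singular;
2. every intracellular reaction and pseudo-sink is replicated per region;
   a copy catalysed by enzyme E in region *k* is bounded by
   0 ≤ v ≤ *k*<sub>cat,E</sub>[E]<sub>k</sub>, where [E]<sub>k</sub> is the
   region's allocated share of the enzyme total;
3. cross-membrane transport reactions are replicated once per *boundary*
   region (one transport per metabolite per boundary region, since the
   medium is a single pool); exchange reactions touching only extracellular
   species stay whole-cell;
4. for each metabolite allowed to diffuse, two opposed directed variables
   per 4-connected neighbour pair carry flux with stoichiometry −1 at the
   source region and +1 at the target, lower bound 0 — one variable per
   direction is what keeps all diffusion fluxes non-negative;
5. a cell-scale objective weight *w* on reaction *r* becomes weight *w* on
   every regional copy, so the optimum is the whole-cell total.

Steady state (**Sv** = 0 over all regional species) and linearity are
inherited from FBA. There is no notion of concentration: diffusion fluxes
are free variables the optimiser sets, not Fick's-law responses to
gradients. The two rate-limiting regimes are the extremes — *instantaneous*
(diffusion variables unbounded above) and *none* (variables omitted
entirely, which is equivalent to pinning them at zero but keeps the LP
smaller). A finite per-edge cap is also accepted for intermediate regimes.

Pseudo-product species (Biomass, Energy, Toxin) are declared cellular so
their sinks are replicated per region, but they are never given diffusion
variables: each region has its own unbounded sink, so diffusing them could
never change the optimum, and the regimes of interest only ever vary the
pathway intermediates.

## Geometry

Region (i, j) of an *I* × *J* grid has layer index
min(i, j, I−1−i, J−1−j): layer 0 is the boundary ring, deeper layers are
concentric rectangular peels. Adjacency is 4-connected (edge-sharing
squares); diagonal diffusion is excluded. The perimeter-to-area (PA) ratio
— boundary regions over total regions — is the 2-D proxy of
surface-to-volume ratio used to compare shapes. The five built-in shape
presets (1×36, 2×18, 3×12, 4×9, 6×6) all contain 36 regions, so they share
one spatial resolution and differ only in shape; 1×36 and 2×18 both have
PA ratio 1 and are distinguishable only at finer resolution.

## Enzyme allocation

An enzyme total [E] is split over its scope K<sub>E</sub> (all regions for
enzymes, the boundary layer for transporters) proportionally to
non-negative weights n<sub>k</sub>:

* uniform: n = 1;
* positive gradient: n = 1 on the outermost layer in scope, increasing by
  the gradient parameter per layer toward the centre (centre-rich);
* negative gradient: the mirror — n = 1 on the innermost layer, increasing
  by the parameter magnitude per layer toward the boundary (boundary-rich);
* random: n ~ Uniform(0, 1) i.i.d. per region.

The sign of the gradient parameter selects direction through the choice of
pattern; its magnitude (default 1) sets steepness. Taking the magnitude,
rather than adding a signed increment literally, is deliberate: a literal
"increase by −1 per layer" would drive n<sub>k</sub> negative, which the
proportional-split rule forbids. On a single-layer scope (the boundary, or
any 1×J grid) both gradients degenerate to uniform, so boundary-scope
transporters meaningfully support only uniform and random patterns. The
uniform sampling distribution for random weights is the minimal assumption;
any alternative can be had by allocating externally and passing the result
to the discretiser. Allocation conserves mass to relative 1e−9 by
construction for every pattern and seed.

## Solving and numerical choices

The LP (maximise **c**ᵀ**v**, **Sv** = 0, bounds) is assembled as a scipy
sparse matrix with a deterministic variable order — reactions in
declaration order, regions row-major, then diffusion edges by metabolite,
pair and direction — and solved with HiGHS via `scipy.optimize.linprog`.
Identical models therefore yield identical solutions across runs.
Infeasibility and unboundedness are reported as solution statuses, never
raised. Tolerances: steady-state residual ≤ 1e−6 (checked by
`verify_steady_state`), bound feasibility 1e−9; both are orders of
magnitude below the O(100) flux scale of the built-in models. Only the
objective value is unique in general; per-region fluxes can be degenerate,
so all shipped analyses either aggregate regional copies back to cell-scale
totals (invariant whenever the objective is) or pin the split by
construction (the maximal flux-ratio case is forced by opposing gradient
capacities). An optional parsimonious post-step (fix *Z*, minimise total
absolute flux) is available but off by default — none of the reported
quantities need it.

## Experiments and what they show

Deterministic sweeps cross shape × diffusion regime × pattern combination;
stochastic batches run *n* = 100 replicates, redrawing the allocation of
every random-patterned enzyme each replicate while deterministic patterns
stay fixed, and report mean, standard deviation and CV = std/mean. CV uses
the sample standard deviation (n−1 denominator) — the choice is
documented here because either convention is defensible; at n = 100 the
difference is below the reporting precision. Batches are seeded for
reproducibility; robustness across seeds is itself a tested property
(CV stable to Monte-Carlo error between seeds).

The built-in toy models *are* the study conditions: parameter sets printed
in full (totals 100, kcat 1.0 except E7's 2.0, uptake caps 100), chosen so
that at cell scale no single enzyme is limiting. What the test battery
demonstrates is therefore about the method, not about any real organism:
that the expansion is exact on a 1×1 grid, that instantaneous diffusion
recovers the cell-scale optimum independent of shape, that adding
diffusion variables can only relax the LP, and that diffusion limitation
couples growth/energy to shape and enzyme placement in the expected
directions. Real metabolic networks are far larger, metabolites are never
perfectly immobile, and enzyme placement is not static — so magnitudes here
bound the phenomenon rather than predict particular cells.

## Known limitations

* Rectangular 2-D grids only; no organelles or membrane-bounded
  sub-compartments (a region's exchanges with neighbours are always
  diffusion, never regulated transport).
* No concentration variables, hence no gradient-driven diffusion rates and
  no crowding effects; diffusion is either free, capped, or absent.
* Multi-objective handling is fixed-weight linear scalarisation; the
  (+1, −2) energy/toxin weighting is exposed in the model definition but
  not swept.
* Gene–protein–reaction rules, thermodynamic constraints and genome-scale
  reconstructions are out of scope; SBML-FBC import covers network,
  bounds and objective, with catalyst/kcat supplied separately since FBC
  has no slot for them.
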