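import pytest

from gridfba import (
    DiffusionPolicy,
    DistributionPattern,
    allocate,
    build_branched_model,
    build_grid,
    build_linear_model,
    discretise,
)


@pytest.fixture
def linear_model():
    return build_linear_model()


@pytest.fixture
def branched_model():
    return build_branched_model()


@pytest.fixture
def grid66():
    return build_grid(6, 6)


def uniform_allocations(model, grid):
    """Uniform allocation for every enzyme; transporters on the boundary only."""
    transporters = {
        r.catalyst for r in model.reactions if r.kind == "transport" and r.catalyst
    }
    out = {}
    for enz in model.enzymes:
        scope = "boundary_only" if enz.id in transporters else "all_regions"
        out[enz.id] = allocate(enz, DistributionPattern("uniform", scope=scope), grid)
    return out


def discretise_uniform(model, grid, diffusible=()):
    """Discretise with uniform allocations and the given diffusible metabolites."""
    return discretise(
        model,
        grid,
        uniform_allocations(model, grid),
        DiffusionPolicy.instantaneous_for(diffusible),
    )
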