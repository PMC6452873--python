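import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from undermet import (
    LARGE_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    make_planted_scenario,
    make_toy_model,
)


@pytest.fixture
def chain_model():
    """Linear chain EX_A (lb -10) -> A -> biomass, yield 1: optimum 10."""
    return MetabolicModel(
        metabolites=[Metabolite("a_e", compartment="e"), Metabolite("a_c", compartment="c")],
        reactions=[
            Reaction("EX_a_e", {"a_e": -1.0}, lower_bound=-10.0, upper_bound=LARGE_BOUND,
                     tags={"exchange"}),
            Reaction("TPT", {"a_e": -1.0, "a_c": 1.0}, lower_bound=0.0,
                     upper_bound=LARGE_BOUND, gpr="g_t"),
            Reaction("BIOMASS", {"a_c": -1.0}, lower_bound=0.0, upper_bound=LARGE_BOUND,
                     tags={"biomass"}),
        ],
        genes={"g_t"},
        objective_id="BIOMASS",
        id="chain",
    )


@pytest.fixture
def parallel_model():
    """A -> B direct (one reaction) vs A -> C -> B (two reactions); both feed biomass."""
    return MetabolicModel(
        metabolites=[
            Metabolite("a_e", compartment="e"),
            Metabolite("a_c", compartment="c"),
            Metabolite("c_c", compartment="c"),
            Metabolite("b_c", compartment="c"),
        ],
        reactions=[
            Reaction("EX_a_e", {"a_e": -1.0}, lower_bound=-10.0, upper_bound=LARGE_BOUND,
                     tags={"exchange"}),
            Reaction("TPT", {"a_e": -1.0, "a_c": 1.0}, lower_bound=0.0,
                     upper_bound=LARGE_BOUND),
            Reaction("DIRECT", {"a_c": -1.0, "b_c": 1.0}, lower_bound=0.0,
                     upper_bound=LARGE_BOUND, gpr="g_direct"),
            Reaction("VIA1", {"a_c": -1.0, "c_c": 1.0}, lower_bound=0.0,
                     upper_bound=LARGE_BOUND, gpr="g_via1"),
            Reaction("VIA2", {"c_c": -1.0, "b_c": 1.0}, lower_bound=0.0,
                     upper_bound=LARGE_BOUND, gpr="g_via2"),
            Reaction("BIOMASS", {"b_c": -1.0}, lower_bound=0.0, upper_bound=LARGE_BOUND,
                     tags={"biomass"}),
        ],
        genes={"g_direct", "g_via1", "g_via2"},
        objective_id="BIOMASS",
        id="parallel",
    )


@pytest.fixture
def toy_model():
    return make_toy_model(n_branches=2, seed=1)


@pytest.fixture
def planted_scenario():
    return make_planted_scenario(n_branches=2, n_substrates=1, seed=3)


def random_toy_models(n_models: int, seed: int = 0):
    """Seeded stream of varied toy models for property tests."""
    rng = np.random.default_rng(seed)
    return [
        make_toy_model(n_branches=int(rng.integers(1, 4)), seed=int(rng.integers(1 << 16)))
        for _ in range(n_models)
    ]
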