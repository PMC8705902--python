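import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutflux.core import MetabolicModel, Metabolite, Reaction
from gutflux.synth import generate_scenario

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def chain_model() -> MetabolicModel:
    """A -> B chain with bounded A supply: FBA optimum on EX_B is 10."""
    m = MetabolicModel(id="chain")
    m.add_compartment("c")
    for mid in ("A", "B"):
        m.add_metabolite(Metabolite(mid, "c"))
    m.add_reaction(Reaction("EX_A", {("A", "c"): -1.0}, lb=-10, ub=0,
                            kind="exchange"))
    m.add_reaction(Reaction("C1", {("A", "c"): -1.0, ("B", "c"): 1.0},
                            lb=0, ub=1000))
    m.add_reaction(Reaction("EX_B", {("B", "c"): -1.0}, lb=0, ub=1000,
                            kind="exchange"))
    m.objective = {"EX_B": 1.0}
    return m


@pytest.fixture(scope="session")
def default_bundle():
    """The default 10-strain, 7-timepoint synthetic study."""
    return generate_scenario(seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
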