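import numpy as np
import pytest

from apopnet.dose_response import find_critical_dose
from apopnet.sensitivity import SensitivityConfig, build_spectrum
from apopnet.synthetic import ToyModelConfig, make_toy_network


@pytest.fixture(scope="session")
def toy():
    """Reference toy model (exact rates, validated switch)."""
    return make_toy_network(ToyModelConfig())


@pytest.fixture(scope="session")
def toy_cd(toy):
    """Critical dose of the reference toy model."""
    res = find_critical_dose(toy.network, toy.executioner_id)
    assert res.apoptosis_achievable
    return res


@pytest.fixture(scope="session")
def toy_spectrum(toy):
    """Full sensitivity spectrum of the reference toy model (shared: ~15 s)."""
    return build_spectrum(toy.network, config=SensitivityConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


def random_network(rng, n_species=5, n_reactions=8, max_stoich=2):
    """A random small mass-action network for oracle-based tests."""
    from apopnet.network import RateParameter, ReactionDef, ReactionNetwork, SpeciesDef

    species = [
        SpeciesDef(id=f"S{i}", initial_amount=float(rng.uniform(0, 2)))
        for i in range(n_species)
    ]
    params = [
        RateParameter(id=f"k{j}", value=float(rng.uniform(0.1, 3.0)))
        for j in range(n_reactions)
    ]
    reactions = []
    for j in range(n_reactions):
        n_react = int(rng.integers(1, 3))
        reactants = {}
        for _ in range(n_react):
            sid = f"S{int(rng.integers(n_species))}"
            reactants[sid] = reactants.get(sid, 0) + int(rng.integers(1, max_stoich + 1))
        products = {f"S{int(rng.integers(n_species))}": int(rng.integers(1, max_stoich + 1))}
        reactions.append(ReactionDef(id=f"r{j}", rate_constant_id=f"k{j}",
                                     reactants=reactants, products=products))
    return ReactionNetwork(species, reactions, params)
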