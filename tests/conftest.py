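"""Shared fixtures: toy networks and a small synthetic study universe."""

import pytest

from phenolnet.network import Metabolite, MetabolicNetwork, Reaction
from phenolnet.synthetic import generate_universe, plant_pathways


@pytest.fixture
def chain_net() -> MetabolicNetwork:
    """Linear chain: EX_A (source, 0..10) -> A -> B -> EX_B."""
    return MetabolicNetwork(
        [Metabolite("A"), Metabolite("B")],
        [Reaction("EX_A", {"A": 1}, lower_bound=0, upper_bound=10),
         Reaction("R1", {"A": -1, "B": 1}),
         Reaction("EX_B", {"B": -1})])


@pytest.fixture
def toy_universal() -> MetabolicNetwork:
    """Three reactions for filtering: taxa and InChI coverage differ.

    R_ok has taxa and fully structured metabolites; R_no_taxa lacks taxa;
    R_no_inchi touches a structureless metabolite.
    """
    return MetabolicNetwork(
        [Metabolite("a", inchi="InChI=1S/H2O/h1H2"),
         Metabolite("b", inchi="InChI=1S/CH4O/c1-2/h2H,1H3"),
         Metabolite("c")],  # no InChI
        [Reaction("R_ok", {"a": -1, "b": 1}, taxa={"s1"}),
         Reaction("R_no_taxa", {"a": -1, "b": 1, "c": 1}),
         Reaction("R_no_inchi", {"b": -1, "c": 1}, taxa={"s2"})])


@pytest.fixture(scope="session")
def small_study():
    """One generated universe with planted depth-2 pathways (seed 7)."""
    net = generate_universe(n_species=4, n_metabolites=40, connectivity=0.4,
                            seed=7)
    truth = plant_pathways(net, n_sources=2, depth=2, seed=7)
    return net, truth
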