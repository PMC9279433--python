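"""Network data model, I/O round trips, universal-database construction."""

from fractions import Fraction

import pytest

from phenolnet.io import (formula_to_map, load_network, map_to_formula,
                          write_network)
from phenolnet.network import (Metabolite, MetabolicNetwork, Reaction,
                               ValidationError, filter_universal,
                               merge_with_dedup, summarize)


class TestInvariants:
    def test_negative_formula_count_rejected(self):
        with pytest.raises(ValidationError):
            Metabolite("x", formula={"C": -1})

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ValidationError):
            Reaction("r", {})

    def test_bounds_must_match_reversibility(self):
        with pytest.raises(ValidationError):
            Reaction("r", {"a": -1}, reversible=False, lower_bound=-5,
                     upper_bound=5)
        with pytest.raises(ValidationError):
            Reaction("r", {"a": -1}, reversible=True, lower_bound=0,
                     upper_bound=5)

    def test_default_bounds(self):
        r_irr = Reaction("r", {"a": -1})
        assert (r_irr.lower_bound, r_irr.upper_bound) == (0.0, 1000.0)
        r_rev = Reaction("r", {"a": -1}, reversible=True)
        assert (r_rev.lower_bound, r_rev.upper_bound) == (-1000.0, 1000.0)

    def test_dangling_metabolite_reference_rejected(self):
        net = MetabolicNetwork([Metabolite("a")])
        with pytest.raises(ValidationError, match="undeclared"):
            net.add_reaction(Reaction("r", {"a": -1, "ghost": 1}))

    def test_stoichiometric_matrix_roundtrip(self, chain_net):
        S, mets, rxns = chain_net.stoichiometric_matrix()
        assert S.shape == (2, 3)
        j = rxns.index("R1")
        assert S[mets.index("A"), j] == -1 and S[mets.index("B"), j] == 1


class TestFormulaStrings:
    @pytest.mark.parametrize("text, expected", [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("CHCl3", {"C": 1, "H": 1, "Cl": 3}),
    ])
    def test_parse(self, text, expected):
        assert formula_to_map(text) == expected

    def test_roundtrip_hill_order(self):
        assert map_to_formula({"O": 6, "C": 6, "H": 12}) == "C6H12O6"

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            formula_to_map("1C6")


class TestIO:
    @pytest.mark.parametrize("dialect", ["tsv", "sbml"])
    def test_write_load_roundtrip(self, toy_universal, tmp_path, dialect):
        path = tmp_path / ("net" if dialect == "tsv" else "net.xml")
        write_network(toy_universal, path, dialect=dialect)
        again = load_network(path, dialect=dialect)
        assert again == toy_universal
        # write(load(x)) == load(x): a second cycle is stable too
        path2 = tmp_path / ("net2" if dialect == "tsv" else "net2.xml")
        write_network(again, path2, dialect=dialect)
        assert load_network(path2, dialect=dialect) == again

    def test_toy_fixture_counts(self, toy_universal, tmp_path):
        write_network(toy_universal, tmp_path / "toy", dialect="tsv")
        net = load_network(tmp_path / "toy", dialect="tsv")
        assert len(net.reactions) == 3 and len(net.metabolites) == 3

    def test_malformed_file_names_line(self, tmp_path):
        mpath = tmp_path / "bad.metabolites.tsv"
        mpath.write_text("id\tname\tinchi\tsmiles\tformula\tcompartment\n"
                         "m1\tok\t\t\t\tc\n")
        (tmp_path / "bad.reactions.tsv").write_text(
            "id\tstoichiometry\treversible\tlower_bound\tupper_bound\ttaxa"
            "\tec_numbers\tprovenance\n"
            "r1\tm1:zzz\t0\t0\t10\t\t\tannotated\n")
        with pytest.raises(ValidationError, match="r1"):
            load_network(tmp_path / "bad", dialect="tsv")

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            load_network(tmp_path / "x", dialect="yaml")


class TestFilterUniversal:
    def test_hand_enumerated_fixture(self, toy_universal):
        out = filter_universal(toy_universal, {"s1", "s2"})
        # R_no_taxa has no taxa; R_no_inchi touches InChI-less metabolite c
        assert set(out.reactions) == {"R_ok"}
        assert set(out.metabolites) == {"a", "b"}

    def test_noop_when_everything_qualifies(self):
        net = MetabolicNetwork(
            [Metabolite("a", inchi="InChI=1S/H2O/h1H2")],
            [Reaction("r", {"a": -1}, taxa={"s1"})])
        out = filter_universal(net, {"s1"})
        assert out == net

    def test_disjoint_taxa_empty_result(self, toy_universal):
        out = filter_universal(toy_universal, {"nobody"})
        assert not out.reactions and not out.metabolites

    def test_idempotent(self, toy_universal):
        once = filter_universal(toy_universal, {"s1"})
        twice = filter_universal(once, {"s1"})
        assert once == twice

    def test_empty_taxa_rejected(self, toy_universal):
        with pytest.raises(ValueError):
            filter_universal(toy_universal, set())


WATER = "InChI=1S/H2O/h1H2"


class TestMerge:
    def test_idempotence(self, toy_universal):
        merged, _ = merge_with_dedup(toy_universal, toy_universal)
        assert len(merged.reactions) == len(toy_universal.reactions)
        assert len(merged.metabolites) == len(toy_universal.metabolites)

    def test_shared_water_under_different_ids(self):
        a = MetabolicNetwork([Metabolite("h2o", inchi=WATER)],
                             [Reaction("ra", {"h2o": -1}, taxa={"s1"})])
        b = MetabolicNetwork([Metabolite("water", inchi=WATER)],
                             [Reaction("rb", {"water": 1}, taxa={"s2"})])
        merged, conflicts = merge_with_dedup(a, b)
        assert len(merged.metabolites) == 1
        assert not conflicts

    def test_duplicate_reaction_unions_taxa(self):
        def make(taxa):
            return MetabolicNetwork(
                [Metabolite("h2o", inchi=WATER),
                 Metabolite("x", inchi="InChI=1S/CH4O/c1-2/h2H,1H3")],
                [Reaction("r", {"h2o": -1, "x": 1}, taxa=taxa)])
        merged, _ = merge_with_dedup(make({"s1"}), make({"s2"}))
        assert len(merged.reactions) == 1
        assert next(iter(merged.reactions.values())).taxa == {"s1", "s2"}

    def test_formula_conflict_reported_structure_wins(self):
        a = MetabolicNetwork([Metabolite("m1", inchi=WATER,
                                         formula={"H": 2, "O": 1})])
        b = MetabolicNetwork([Metabolite("m2", inchi=WATER,
                                         formula={"H": 2, "O": 2})])
        merged, conflicts = merge_with_dedup(a, b)
        assert len(conflicts) == 1
        assert merged.metabolites["m1"].formula == {"H": 2, "O": 1}

    def test_commutative_up_to_relabelling(self):
        a = MetabolicNetwork([Metabolite("h2o", inchi=WATER)],
                             [Reaction("ra", {"h2o": -1}, taxa={"s1"})])
        b = MetabolicNetwork([Metabolite("water", inchi=WATER)],
                             [Reaction("rb", {"water": 1}, taxa={"s2"})])
        ab, _ = merge_with_dedup(a, b)
        ba, _ = merge_with_dedup(b, a)
        assert len(ab.reactions) == len(ba.reactions)
        assert ({m.inchi for m in ab.metabolites.values()}
                == {m.inchi for m in ba.metabolites.values()})


class TestSummarize:
    def test_empty_network(self):
        s = summarize(MetabolicNetwork())
        assert s["n_metabolites"] == 0 and s["n_reactions"] == 0
        assert s["by_provenance"] == {} and s["by_phylum"] == {}

    def test_provenance_counts(self):
        net = MetabolicNetwork(
            [Metabolite("a")],
            [Reaction(f"p{i}", {"a": 1}, provenance="predicted")
             for i in range(2)]
            + [Reaction(f"a{i}", {"a": -1}, provenance="annotated")
               for i in range(3)])
        s = summarize(net)
        assert s["by_provenance"] == {"predicted": 2, "annotated": 3}

    def test_unknown_species_counted_unclassified(self):
        net = MetabolicNetwork([Metabolite("a")],
                               [Reaction("r", {"a": 1}, taxa={"sX"})])
        s = summarize(net, species_to_phylum={"sY": "Firmicutes"})
        assert s["by_phylum"] == {"unclassified": 1}


class TestFormulaProperty:
    def test_formula_roundtrip_property(self):
        from hypothesis import given, settings, strategies as st

        elements = st.sampled_from(["C", "H", "O", "N", "P", "S", "Cl", "Fe"])
        formula_maps = st.dictionaries(elements, st.integers(1, 99),
                                       min_size=1, max_size=6)

        @settings(derandomize=True, max_examples=100)
        @given(formula_maps)
        def roundtrip(formula):
            assert formula_to_map(map_to_formula(formula)) == formula

        roundtrip()
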