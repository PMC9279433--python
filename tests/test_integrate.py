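"""Sequential gap-filling, pruning, single-species repair, version diff."""

import pytest

from phenolnet.fluxlp import FluxProblem, blocked_reactions
from phenolnet.integrate import (coverage_and_diff_report, prune_and_consistency,
                                 sequential_gapfill, single_species_repair)
from phenolnet.network import Metabolite, MetabolicNetwork, Reaction
from phenolnet.synthetic import (extended_universal, generate_universe,
                                 plant_pathways)


def _mini_universal():
    """Base chain plus a predicted reaction needing one universal supplier.

    Base: EX_A -> A -> B -> EX_B.  Prediction for compound X: X + B -> P,
    with uptake machinery for X and an exchange for P available only in the
    universal network.
    """
    mets = [Metabolite(m) for m in ("A", "B", "X", "P")]
    base_rxns = [
        Reaction("EX_A", {"A": 1}, upper_bound=10),
        Reaction("R_AB", {"A": -1, "B": 1}, taxa={"s1"}),
        Reaction("EX_B", {"B": -1}),
    ]
    extra = [
        Reaction("EX_X", {"X": 1}, upper_bound=10, provenance="exchange"),
        Reaction("R_pred_X", {"X": -1, "B": -1, "P": 1}, taxa={"s2"},
                 provenance="predicted"),
        Reaction("EX_P", {"P": -1}, provenance="exchange"),
    ]
    universal = MetabolicNetwork(mets, base_rxns + extra)
    base = MetabolicNetwork([m for m in mets if m.id in "AB"], base_rxns)
    return universal, base


class TestSequentialGapfill:
    def test_supplier_reactions_pulled_in(self):
        universal, base = _mini_universal()
        net, report = sequential_gapfill(universal, base,
                                         {"X": ["R_pred_X"]})
        assert report.integrated == ["X"]
        assert {"R_pred_X", "EX_X", "EX_P"} <= set(net.reactions)
        assert set(base.reactions) <= set(net.reactions)

    def test_no_predictions_returns_base(self):
        universal, base = _mini_universal()
        net, report = sequential_gapfill(universal, base, {})
        assert set(net.reactions) == set(base.reactions)
        assert not report.integrated and not report.skipped

    def test_base_not_subset_raises(self):
        universal, base = _mini_universal()
        stranger = MetabolicNetwork([Metabolite("Z")],
                                    [Reaction("R_z", {"Z": 1})])
        with pytest.raises(ValueError, match="subset"):
            sequential_gapfill(universal, stranger, {})

    def test_infeasible_compound_skipped_not_fatal(self):
        universal, base = _mini_universal()
        universal = universal.copy()
        universal.add_metabolite(Metabolite("Q"))
        universal.add_reaction(Reaction("R_dead", {"Q": -1, "P": 1},
                                        provenance="predicted"))
        net, report = sequential_gapfill(universal, base,
                                         {"X": ["R_pred_X"],
                                          "DeadCompound": ["R_dead"]})
        assert report.integrated == ["X"]
        assert "DeadCompound" in report.skipped


class TestPruneAndConsistency:
    def test_unannotated_linker_cascades(self):
        """Removing an unannotated linker also removes what it stranded."""
        net = MetabolicNetwork(
            [Metabolite(m) for m in ("A", "B", "C")],
            [Reaction("EX_A", {"A": 1}, upper_bound=10),
             Reaction("R_link", {"A": -1, "B": 1}),          # no taxa
             Reaction("R_down", {"B": -1, "C": 1}, taxa={"s1"}),
             Reaction("EX_C", {"C": -1}),
             Reaction("EX_A_drain", {"A": -1})])
        out = prune_and_consistency(net)
        assert "R_link" not in out.reactions
        assert "R_down" not in out.reactions  # blocked once the linker is gone
        assert blocked_reactions(FluxProblem.from_network(out)) == set()

    def test_clean_network_unchanged(self, chain_net):
        net = MetabolicNetwork(
            list(chain_net.metabolites.values()),
            [Reaction("EX_A", {"A": 1}, lower_bound=0, upper_bound=10),
             Reaction("R1", {"A": -1, "B": 1}, taxa={"s1"}),
             Reaction("EX_B", {"B": -1})])
        out = prune_and_consistency(net)
        assert set(out.reactions) == set(net.reactions)


class TestSingleSpeciesRepair:
    def _net_with_dead_end(self):
        """Species s2 produces P[c] but has no way to dispose of it."""
        return MetabolicNetwork(
            [Metabolite("A[c]", compartment="c"),
             Metabolite("A[e]", compartment="e"),
             Metabolite("P[c]", compartment="c")],
            [Reaction("EX_A", {"A[e]": -1}, reversible=True,
                      provenance="exchange"),
             Reaction("T_A", {"A[e]": -1, "A[c]": 1}, reversible=True,
                      taxa={"s2"}, provenance="transport"),
             Reaction("R_AP", {"A[c]": -1, "P[c]": 1}, taxa={"s2"})])

    def test_evidence_adds_transport_and_exchange(self):
        net = self._net_with_dead_end()
        out = single_species_repair(net, evidence={("s2", "P")})
        assert "T_P_s2" in out.reactions and "EX_P" in out.reactions
        assert "R_AP" in out.reactions
        assert blocked_reactions(FluxProblem.from_network(out)) == set()

    def test_no_evidence_removes_stranded_reaction(self):
        net = self._net_with_dead_end()
        out = single_species_repair(net, evidence=set())
        assert "R_AP" not in out.reactions

    def test_clean_species_unchanged(self, small_study):
        net, _ = small_study
        out = single_species_repair(net, evidence=set())
        assert set(out.reactions) == set(net.reactions)


class TestCoverageReport:
    def _catalogue(self):
        """Phenol-Explorer-style sub-class catalogue with printed counts.

        Isoflavonoids 12 -> 36 of 86; anthocyanins 19 -> 38 of 49;
        hydroxycinnamic acids 13 -> 21 of 33.
        """
        classes = {}
        nets = {"old": set(), "new": set()}
        for sub, total, n_old, n_new in [
                ("isoflavonoids", 86, 12, 36),
                ("anthocyanins", 49, 19, 38),
                ("hydroxycinnamic acids", 33, 13, 21)]:
            for i in range(total):
                cid = f"{sub[:4]}_{i:03d}"
                classes[cid] = (sub, total)
                if i < n_old:
                    nets["old"].add(cid)
                if i < n_new:
                    nets["new"].add(cid)
        def to_net(ids):
            return MetabolicNetwork([Metabolite(f"{c}[c]", compartment="c")
                                     for c in sorted(ids)])
        return to_net(nets["old"]), to_net(nets["new"]), classes

    def test_worked_percentage_point_differences(self):
        old, new, classes = self._catalogue()
        report = coverage_and_diff_report(old, new, classes)
        diffs = {sub: rec["coverage_diff_pct"]
                 for sub, rec in report["by_subclass"].items()}
        assert diffs == {"isoflavonoids": 28, "anthocyanins": 39,
                         "hydroxycinnamic acids": 24}

    def test_identical_networks_all_zero(self):
        old, _, classes = self._catalogue()
        report = coverage_and_diff_report(old, old, classes)
        assert report["n_added_metabolites"] == 0
        assert report["n_added_reactions"] == 0
        assert all(rec["coverage_diff_pct"] == 0
                   for rec in report["by_subclass"].values())

    def test_unclassified_compound_counted(self):
        old, new, classes = self._catalogue()
        report = coverage_and_diff_report(old, new, classes,
                                          species_to_phylum={})
        assert "unclassified" not in report["by_subclass"]  # all classified


class TestPipelineDeterminism:
    def test_identical_inputs_identical_serialization(self, tmp_path):
        from phenolnet.io import write_network
        nets = []
        for _ in range(2):
            net = generate_universe(3, 30, 0.3, seed=11)
            truth = plant_pathways(net, 1, 1, seed=11)
            ext = extended_universal(net, truth)
            preds = {s: [r.id for r in truth.hidden_reactions[s]
                         + truth.support_reactions[s]]
                     for s in truth.sources}
            out, _ = sequential_gapfill(ext, net, preds)
            out = prune_and_consistency(out)
            nets.append(out)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_network(nets[0], p1)
        write_network(nets[1], p2)
        for suffix in (".metabolites.tsv", ".reactions.tsv"):
            assert (tmp_path / f"a{suffix}").read_bytes() == \
                   (tmp_path / f"b{suffix}").read_bytes()

    def test_base_preserved_through_full_pipeline(self, small_study):
        net, truth = small_study
        ext = extended_universal(net, truth)
        preds = {s: [r.id for r in truth.hidden_reactions[s]
                     + truth.support_reactions[s]] for s in truth.sources}
        out, report = sequential_gapfill(ext, net, preds)
        out = prune_and_consistency(out)
        out = single_species_repair(out, evidence=set())
        assert set(net.reactions) <= set(out.reactions)
        assert report.integrated == sorted(truth.sources)
        # no blocked reactions, no unannotated non-exchange reactions
        assert blocked_reactions(FluxProblem.from_network(out)) == set()
        for rid, r in out.reactions.items():
            assert r.taxa or len(r.stoichiometry) == 1
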