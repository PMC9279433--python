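"""FVA, blocked reactions and weighted FASTCORE against independent oracles.

The FVA oracle enumerates polytope vertices (active-bound combinations on
the null space of S); the FASTCORE oracle searches all subsets of non-core
reactions exhaustively, checking flux consistency of each candidate set with
direct ``scipy.optimize.linprog`` calls — a code path fully independent of
the implementation under test.
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from phenolnet.fluxlp import (CoreInfeasibleError, FluxProblem, GapfillSpec,
                              InfeasibleProblemError, blocked_reactions,
                              fastcore_weighted, fva)
from phenolnet.network import Metabolite, MetabolicNetwork, Reaction


# ---------------------------------------------------------------------------
# oracles


def fva_vertex_oracle(S, lb, ub, tol=1e-9):
    """Per-coordinate min/max over enumerated vertices of {Sv=0, lb<=v<=ub}."""
    S = np.atleast_2d(np.asarray(S, float))
    m, n = S.shape
    d = n - np.linalg.matrix_rank(S) if S.size else n
    vertices = []
    for combo in itertools.combinations(range(n), d):
        for vals in itertools.product(*[(lb[i], ub[i]) for i in combo]):
            A = np.vstack([S] + [np.eye(n)[i] for i in combo])
            b = np.concatenate([np.zeros(m), np.array(vals)])
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if (np.allclose(A @ v, b, atol=tol)
                    and np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7)):
                vertices.append(v)
    assert vertices, "oracle found no feasible vertex"
    V = np.array(vertices)
    return V.min(axis=0), V.max(axis=0)


def _consistent_subset(S, lb, ub, cols, eps=1e-4):
    """True iff every reaction in cols can carry |flux| >= eps within cols."""
    cols = sorted(cols)
    Ssub = S[:, cols]
    for k, j in enumerate(cols):
        ok = False
        for sign in (-1.0, 1.0):
            c = np.zeros(len(cols))
            c[k] = sign
            res = linprog(c, A_eq=Ssub, b_eq=np.zeros(S.shape[0]),
                          bounds=list(zip(lb[cols], ub[cols])), method="highs")
            if res.status == 0 and res.fun <= -eps:
                ok = True
                break
        if not ok:
            return False
    return True


def fastcore_subset_oracle(p: FluxProblem, spec: GapfillSpec):
    """Minimum non-core weight over all consistent supersets of the core."""
    idx = {r: i for i, r in enumerate(p.reaction_ids)}
    core = sorted(idx[r] for r in spec.core)
    noncore = sorted(set(range(p.n_reactions)) - set(core))
    lb, ub = np.asarray(p.lb), np.asarray(p.ub)
    best = None
    for r in range(len(noncore) + 1):
        for extra in itertools.combinations(noncore, r):
            cols = core + list(extra)
            w = sum(spec.weight(p.reaction_ids[j]) for j in extra)
            if best is not None and w >= best[0]:
                continue
            if _consistent_subset(p.S, lb, ub, cols):
                best = (w, set(cols))
    return best


# ---------------------------------------------------------------------------
# fixtures


def _problem(net):
    return FluxProblem.from_network(net)


@pytest.fixture
def loop_net():
    """Reversible isolated loop A<->B plus closed exchanges."""
    return MetabolicNetwork(
        [Metabolite("A"), Metabolite("B")],
        [Reaction("L1", {"A": -1, "B": 1}, reversible=True),
         Reaction("L2", {"B": -1, "A": 1}, reversible=True),
         Reaction("EX_A", {"A": -1}, lower_bound=0, upper_bound=0),
         Reaction("EX_B", {"B": -1}, lower_bound=0, upper_bound=0)])


class TestFVA:
    def test_linear_chain_ranges(self, chain_net):
        ranges = fva(_problem(chain_net))
        for rid in ("EX_A", "R1", "EX_B"):
            assert ranges[rid] == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_closed_exchanges_force_zero(self):
        net = MetabolicNetwork(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("EX_A", {"A": 1}, lower_bound=0, upper_bound=0),
             Reaction("R1", {"A": -1, "B": 1}),
             Reaction("EX_B", {"B": -1}, lower_bound=0, upper_bound=0)])
        ranges = fva(_problem(net))
        assert all(lo == pytest.approx(0, abs=1e-6)
                   and hi == pytest.approx(0, abs=1e-6)
                   for lo, hi in ranges.values())

    def test_reversible_loop_carries_flux(self, loop_net):
        ranges = fva(_problem(loop_net))
        assert ranges["L1"] == pytest.approx((-1000.0, 1000.0), abs=1e-6)
        assert ranges["L2"] == pytest.approx((-1000.0, 1000.0), abs=1e-6)
        assert ranges["EX_A"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_infeasible_problem_raises(self):
        # forced production of A with no consumer: Sv=0 unsatisfiable
        net = MetabolicNetwork(
            [Metabolite("A")],
            [Reaction("EX_A", {"A": 1}, lower_bound=5, upper_bound=10)])
        with pytest.raises(InfeasibleProblemError):
            fva(_problem(net))

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_vertex_enumeration_oracle(self, seed):
        """FVA equals the vertex-enumeration oracle on random <=6-reaction nets."""
        rng = np.random.default_rng(seed)
        n_m, n_r = rng.integers(2, 4), rng.integers(3, 7)
        S = rng.integers(-1, 2, size=(n_m, n_r)).astype(float)
        lb = np.where(rng.random(n_r) < 0.5, -10.0, 0.0)
        ub = np.full(n_r, 10.0)
        rxns = [f"r{j}" for j in range(n_r)]
        p = FluxProblem(S, lb, ub, rxns, [f"m{i}" for i in range(n_m)])
        got = fva(p)
        lo, hi = fva_vertex_oracle(S, lb, ub)
        for j, rid in enumerate(rxns):
            assert got[rid][0] == pytest.approx(lo[j], abs=1e-6)
            assert got[rid][1] == pytest.approx(hi[j], abs=1e-6)

    def test_agrees_with_cobrapy_on_fixture(self, chain_net):
        """Independent cross-check of FVA against cobrapy on the toy chain."""
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("toy")
        mets = {m: cobra.Metabolite(m, compartment="c")
                for m in chain_net.metabolites}
        for rid, r in chain_net.reactions.items():
            rxn = cobra.Reaction(rid, lower_bound=r.lower_bound,
                                 upper_bound=r.upper_bound)
            model.add_reactions([rxn])
            rxn.add_metabolites({mets[m]: float(c)
                                 for m, c in r.stoichiometry.items()})
        from cobra.flux_analysis import flux_variability_analysis
        ref = flux_variability_analysis(model, fraction_of_optimum=0)
        got = fva(_problem(chain_net))
        for rid in chain_net.reactions:
            assert got[rid][0] == pytest.approx(ref.loc[rid, "minimum"], abs=1e-6)
            assert got[rid][1] == pytest.approx(ref.loc[rid, "maximum"], abs=1e-6)


class TestBlocked:
    def test_dangling_branch_blocked(self, chain_net):
        net = chain_net.copy()
        net.add_metabolite(Metabolite("C"))
        net.add_reaction(Reaction("R_dead", {"B": -1, "C": 1}))
        assert blocked_reactions(_problem(net)) == {"R_dead"}

    def test_consistent_network_has_none(self, chain_net):
        assert blocked_reactions(_problem(chain_net)) == set()

    def test_fixpoint_after_removal(self, chain_net):
        net = chain_net.copy()
        net.add_metabolite(Metabolite("C"))
        net.add_reaction(Reaction("R_dead", {"B": -1, "C": 1}))
        blocked = blocked_reactions(_problem(net))
        rest = net.subset(set(net.reactions) - blocked)
        assert blocked_reactions(_problem(rest)) == set()


class TestFastcoreWeighted:
    def _route_net(self):
        """Annotated 2-step route (weight 1+1) vs weight-100 shortcut."""
        return MetabolicNetwork(
            [Metabolite("A"), Metabolite("B"), Metabolite("C")],
            [Reaction("EX_A", {"A": 1}, upper_bound=10),
             Reaction("Ra1", {"A": -1, "C": 1}),
             Reaction("Ra2", {"C": -1, "B": 1}),
             Reaction("Rshort", {"A": -1, "B": 1}),
             Reaction("R_core", {"B": -1})])

    def test_prefers_low_weight_route_and_matches_oracle(self):
        net = self._route_net()
        p = _problem(net)
        spec = GapfillSpec(core={"R_core"},
                           weights={"Rshort": 100.0, "Ra1": 1.0,
                                    "Ra2": 1.0, "EX_A": 1.0})
        got = fastcore_weighted(p, spec)
        assert got == {"R_core", "EX_A", "Ra1", "Ra2"}
        w_oracle, _ = fastcore_subset_oracle(p, spec)
        w_got = sum(spec.weight(r) for r in got - spec.core)
        assert w_got == w_oracle

    def test_empty_core_gives_empty_set(self, chain_net):
        assert fastcore_weighted(_problem(chain_net), GapfillSpec(core=set())) == set()

    def test_unsupported_core_raises(self, chain_net):
        net = chain_net.copy()
        net.add_metabolite(Metabolite("D"))
        net.add_reaction(Reaction("R_orphan", {"D": -1, "B": 1}))
        with pytest.raises(CoreInfeasibleError, match="R_orphan"):
            fastcore_weighted(_problem(net), GapfillSpec(core={"R_orphan"}))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_small_nets(self, seed):
        """Selected non-core weight equals the exhaustive-subset optimum."""
        rng = np.random.default_rng(100 + seed)
        # random chain-with-branches networks, <= 8 reactions
        mets = [Metabolite(m) for m in "ABCD"]
        rxns = [Reaction("EX_A", {"A": 1}, upper_bound=10),
                Reaction("EX_D", {"D": -1})]
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C"), ("B", "D"),
                 ("A", "D")]
        weights = {}
        for i, (x, y) in enumerate(edges):
            if rng.random() < 0.75:
                rid = f"R{x}{y}"
                rxns.append(Reaction(rid, {x: -1, y: 1}))
                weights[rid] = float(rng.choice([1.0, 5.0, 100.0]))
        net = MetabolicNetwork(mets, rxns)
        p = _problem(net)
        spec = GapfillSpec(core={"EX_D"}, weights=weights)
        oracle = fastcore_subset_oracle(p, spec)
        if oracle is None:
            with pytest.raises(CoreInfeasibleError):
                fastcore_weighted(p, spec)
            return
        got = fastcore_weighted(p, spec)
        assert spec.core <= got
        sub = p.column_subproblem(got)
        assert blocked_reactions(sub) == set()
        w_got = sum(spec.weight(r) for r in got - spec.core)
        assert w_got == pytest.approx(oracle[0])

    def test_weight_monotonicity(self):
        """Raising a non-core weight never increases its selection frequency."""
        net = self._route_net()
        p = _problem(net)
        selected = []
        for w_short in (0.5, 2.0, 100.0):
            spec = GapfillSpec(core={"R_core"},
                               weights={"Rshort": w_short, "Ra1": 1.0,
                                        "Ra2": 1.0, "EX_A": 1.0})
            selected.append("Rshort" in fastcore_weighted(p, spec))
        # once dropped at some weight, it stays dropped at higher weights
        assert sorted(selected, reverse=True) == selected
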