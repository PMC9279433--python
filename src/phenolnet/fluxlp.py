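"""Stoichiometric LP machinery.

Steady-state flux analysis over ``S v = 0, lb <= v <= ub``: flux variability
analysis (FVA), blocked-reaction detection, and context extraction with the
weighted FASTCORE family of algorithms (LP-7 / LP-10 scheme, per-reaction
weights scaling the sparsity penalty).

All linear programs go through a thin solver adapter (:class:`LPSolver`)
wrapping ``scipy.optimize.linprog`` with the HiGHS backend, so the backend is
swappable without touching the algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = [
    "FluxProblem", "GapfillSpec", "LPSolver",
    "InfeasibleProblemError", "CoreInfeasibleError",
    "fva", "blocked_reactions", "fastcore_weighted",
]

#: flux threshold below which a flux is considered zero
DEFAULT_EPS = 1e-6


class InfeasibleProblemError(RuntimeError):
    """The steady-state polytope is empty (or an FVA sub-LP failed)."""


class CoreInfeasibleError(RuntimeError):
    """A core reaction cannot carry flux in the universal network."""

    def __init__(self, reaction_id: str):
        self.reaction_id = reaction_id
        super().__init__(
            f"core reaction {reaction_id!r} is blocked in the universal network")


class LPSolver:
    """Minimal LP adapter: minimize c·x s.t. A_eq x = b_eq, bounds."""

    method = "highs"

    def solve(self, c, A_eq, b_eq, bounds):
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                      method=self.method)
        return res.status, res.x, res.fun


@dataclass
class FluxProblem:
    """``S v = 0`` with per-reaction bounds; rows metabolites, columns reactions."""

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        m, n = self.S.shape
        if not (len(self.lb) == len(self.ub) == len(self.reaction_ids) == n
                and len(self.metabolite_ids) == m):
            raise ValueError("inconsistent FluxProblem dimensions")
        if np.any(self.lb > self.ub):
            raise ValueError("lb > ub for some reaction")

    @classmethod
    def from_network(cls, net: MetabolicNetwork,
                     eps: float = DEFAULT_EPS) -> "FluxProblem":
        S, mets, rxns = net.stoichiometric_matrix()
        lb = np.array([net.reactions[r].lower_bound for r in rxns])
        ub = np.array([net.reactions[r].upper_bound for r in rxns])
        return cls(S, lb, ub, rxns, mets, eps)

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def column_subproblem(self, reaction_ids: Iterable[str]) -> "FluxProblem":
        idx = [self.reaction_ids.index(r) for r in sorted(set(reaction_ids))]
        keep_rows = np.any(self.S[:, idx] != 0, axis=1)
        return FluxProblem(
            self.S[np.ix_(keep_rows, idx)],
            self.lb[idx], self.ub[idx],
            [self.reaction_ids[j] for j in idx],
            [m for m, k in zip(self.metabolite_ids, keep_rows) if k],
            self.eps)


@dataclass
class GapfillSpec:
    """Core reactions that must be flux-consistent, plus inclusion penalties.

    ``weights`` assigns a nonnegative penalty to each non-core reaction; the
    context extraction heuristically minimizes the total penalty of included
    non-core reactions.  Reactions absent from the map get ``default_weight``.
    """

    core: set[str]
    weights: Mapping[str, float] = field(default_factory=dict)
    default_weight: float = 1.0

    def weight(self, rid: str) -> float:
        w = float(self.weights.get(rid, self.default_weight))
        if w < 0:
            raise ValueError(f"negative weight for reaction {rid!r}")
        return w


def _bounds_list(lb: np.ndarray, ub: np.ndarray) -> list[tuple[float, float]]:
    return list(zip(lb.tolist(), ub.tolist()))


def fva(p: FluxProblem, subset: Sequence[str] | None = None,
        solver: LPSolver | None = None) -> dict[str, tuple[float, float]]:
    """Min and max steady-state flux per reaction over the feasible polytope.

    Raises :class:`InfeasibleProblemError` (naming the first failing LP) when
    the polytope is empty.
    """
    solver = solver or LPSolver()
    rxns = list(subset) if subset is not None else list(p.reaction_ids)
    bounds = _bounds_list(p.lb, p.ub)
    b_eq = np.zeros(p.S.shape[0])
    out: dict[str, tuple[float, float]] = {}
    for rid in rxns:
        j = p.index(rid)
        c = np.zeros(p.n_reactions)
        lo_hi = []
        for sign in (1.0, -1.0):
            c[j] = sign
            status, x, fun = solver.solve(c, p.S, b_eq, bounds)
            if status != 0:
                raise InfeasibleProblemError(
                    f"LP for reaction {rid!r} "
                    f"({'min' if sign > 0 else 'max'}) failed with status "
                    f"{status}")
            lo_hi.append(sign * fun)
        c[j] = 0.0
        vmin, vmax = lo_hi
        out[rid] = (min(vmin, vmax), max(vmin, vmax))
    return out


def blocked_reactions(p: FluxProblem,
                      solver: LPSolver | None = None) -> set[str]:
    """Reactions whose flux is (numerically) zero in every feasible state."""
    ranges = fva(p, solver=solver)
    return {rid for rid, (lo, hi) in ranges.items()
            if abs(lo) <= p.eps and abs(hi) <= p.eps}


# ---------------------------------------------------------------------------
# weighted FASTCORE


def _lp7(p: FluxProblem, J: set[int], lb: np.ndarray, ub: np.ndarray,
         eps: float, solver: LPSolver) -> np.ndarray:
    """Maximize the number of reactions in J carrying flux >= eps.

    max Σ_{j∈J} z_j  s.t.  S v = 0, lb<=v<=ub, z_j <= v_j, 0<=z_j<=eps.
    Implemented as an LP over (v, z).
    """
    n = p.n_reactions
    Jl = sorted(J)
    k = len(Jl)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = np.hstack([p.S, np.zeros((p.S.shape[0], k))])
    # z_j - v_j <= 0  ->  inequality; linprog supports A_ub
    A_ub = np.zeros((k, n + k))
    for i, j in enumerate(Jl):
        A_ub[i, j] = -1.0
        A_ub[i, n + i] = 1.0
    bounds = _bounds_list(lb, ub) + [(0.0, eps)] * k
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(k), A_eq=A_eq,
                  b_eq=np.zeros(p.S.shape[0]), bounds=bounds,
                  method=LPSolver.method)
    if res.status != 0:
        raise InfeasibleProblemError(f"LP-7 failed with status {res.status}")
    return res.x[:n]


def _lp10(p: FluxProblem, K: set[int], P: set[int], weights: np.ndarray,
          lb: np.ndarray, ub: np.ndarray, eps: float,
          solver: LPSolver) -> np.ndarray:
    """Weighted sparsity step: support K while minimizing penalty mass on P.

    min Σ_{p∈P} w_p z_p  s.t.  S v = 0, v_k >= eps (k∈K), |v_p| <= z_p,
    bounds.  The weights scale the L1 sparsity surrogate per reaction.
    """
    n = p.n_reactions
    Pl = sorted(P)
    k = len(Pl)
    c = np.concatenate([np.zeros(n), np.array([weights[j] for j in Pl])])
    A_eq = np.hstack([p.S, np.zeros((p.S.shape[0], k))])
    # v_p - z_p <= 0 and -v_p - z_p <= 0
    A_ub = np.zeros((2 * k, n + k))
    for i, j in enumerate(Pl):
        A_ub[2 * i, j] = 1.0
        A_ub[2 * i, n + i] = -1.0
        A_ub[2 * i + 1, j] = -1.0
        A_ub[2 * i + 1, n + i] = -1.0
    lo = lb.copy()
    for j in K:
        lo[j] = max(lo[j], eps)
    zcap = float(max(np.max(np.abs(lb)), np.max(np.abs(ub)), eps))
    bounds = _bounds_list(lo, ub) + [(0.0, zcap)] * k
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * k), A_eq=A_eq,
                  b_eq=np.zeros(p.S.shape[0]), bounds=bounds,
                  method=LPSolver.method)
    if res.status != 0:
        raise InfeasibleProblemError(f"LP-10 failed with status {res.status}")
    return res.x[:n]


def _find_sparse_mode(p: FluxProblem, J: set[int], P: set[int],
                      singleton: bool, weights: np.ndarray,
                      lb: np.ndarray, ub: np.ndarray, eps: float,
                      solver: LPSolver) -> set[int]:
    if not J:
        return set()
    probe = {min(J)} if singleton else J
    v = _lp7(p, probe, lb, ub, eps, solver)
    K = {j for j in probe if v[j] >= 0.99 * eps}
    if not K:
        return set()
    v = _lp10(p, K, P, weights, lb, ub, eps, solver)
    return {j for j in range(p.n_reactions) if abs(v[j]) >= 0.99 * eps}


def fastcore_weighted(universal: FluxProblem, spec: GapfillSpec,
                      solver: LPSolver | None = None,
                      eps: float = 1e-4) -> set[str]:
    """Extract a flux-consistent reaction set containing the whole core.

    Follows the FASTCORE LP-7/LP-10 scheme with per-reaction weights on the
    sparsity penalty, heuristically minimizing the total weight of included
    non-core reactions.  The result is verified flux-consistent before
    return.  Raises :class:`CoreInfeasibleError` naming the first core
    reaction that cannot carry flux.
    """
    solver = solver or LPSolver()
    if not spec.core:
        return set()
    unknown = spec.core - set(universal.reaction_ids)
    if unknown:
        raise CoreInfeasibleError(sorted(unknown)[0])
    idx = {r: i for i, r in enumerate(universal.reaction_ids)}
    core_idx = {idx[r] for r in spec.core}
    weights = np.array([spec.weight(r) for r in universal.reaction_ids])
    lb = universal.lb.copy()
    ub = universal.ub.copy()
    irrev = {j for j in range(universal.n_reactions) if universal.lb[j] >= 0}

    flipped = False
    singleton = False
    J = core_idx & irrev
    P = set(range(universal.n_reactions)) - core_idx
    A = _find_sparse_mode(universal, J, P, singleton, weights, lb, ub, eps,
                          solver)
    if J - A:
        # an irreversible core reaction cannot carry forward flux
        raise CoreInfeasibleError(universal.reaction_ids[min(J - A)])
    J = core_idx - A
    guard = 0
    while J:
        guard += 1
        if guard > 10 * universal.n_reactions + 100:  # pragma: no cover
            raise InfeasibleProblemError("FASTCORE failed to converge")
        P = P - A
        supp = _find_sparse_mode(universal, J, P, singleton, weights, lb, ub,
                                 eps, solver)
        A |= supp
        if J & A:
            J -= A
            flipped = False
        else:
            probe = {min(J)} if singleton else J
            J_rev = probe - irrev
            if flipped or not J_rev:
                if singleton:
                    raise CoreInfeasibleError(universal.reaction_ids[min(J)])
                flipped = False
                singleton = True
            else:
                for j in J_rev:
                    lb[j], ub[j] = -ub[j], -lb[j]
                flipped = True

    result = {universal.reaction_ids[j] for j in A} | spec.core
    # verification: the extracted context must itself be flux-consistent
    sub = universal.column_subproblem(result)
    blocked = blocked_reactions(sub, solver=solver)
    core_blocked = blocked & spec.core
    if core_blocked:  # pragma: no cover - guarded by the algorithm
        raise CoreInfeasibleError(sorted(core_blocked)[0])
    while blocked:
        result -= blocked
        sub = universal.column_subproblem(result)
        blocked = blocked_reactions(sub, solver=solver)
        if blocked & spec.core:  # pragma: no cover
            raise CoreInfeasibleError(sorted(blocked & spec.core)[0])
    return result
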