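"""Brute-force oracles for the small fixtures.

Every oracle here answers by exhaustive enumeration plus a naively built
feasibility LP, independently of the algorithmic code paths it is used to
check: the stoichiometric system is assembled directly from the cobra
model's reaction/metabolite dictionaries (not via the package's array
extraction) and each candidate answer is tested by a plain feasibility or
single-objective LP.  All oracles are pure functions of their inputs.

These are exponential in the candidate-set size and guarded accordingly;
they exist to certify the LP/MILP implementations on networks of a dozen
reactions, not to run at genome scale.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "brute_force_blocked",
    "brute_force_consistent",
    "brute_force_min_consistent_superset",
    "brute_force_min_gapfill",
    "brute_force_tinit_objective",
]

_CAP = 1e4


def _naive_system(model):
    """(S, lb, ub, reaction ids) assembled straight from the model objects."""
    rids = [r.id for r in model.reactions]
    mids = [m.id for m in model.metabolites]
    mpos = {m: i for i, m in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    lb = np.zeros(len(rids))
    ub = np.zeros(len(rids))
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.metabolites.items():
            S[mpos[met.id], j] = coeff
        lb[j] = max(rxn.lower_bound, -_CAP)
        ub[j] = min(rxn.upper_bound, _CAP)
    return S, lb, ub, rids


def _optimize_flux(S, lb, ub, j, sense):
    c = np.zeros(S.shape[1])
    c[j] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return None
    return float(res.x[j])


def brute_force_blocked(model, tol: float = 1e-6, open_exchange: bool = True, open_bound: float = 1000.0) -> set[str]:
    """Blocked reactions by two LPs per reaction (max then min flux)."""
    S, lb, ub, rids = _naive_system(model)
    if open_exchange:
        exchange = {r.id for r in model.exchanges}
        for j, rid in enumerate(rids):
            if rid in exchange:
                lb[j] = min(lb[j], -abs(open_bound))
    blocked = set()
    for j, rid in enumerate(rids):
        vmax = _optimize_flux(S, lb, ub, j, "max")
        if vmax is None:
            raise RuntimeError("oracle LP infeasible")
        if abs(vmax) > tol:
            continue
        vmin = _optimize_flux(S, lb, ub, j, "min")
        if abs(vmin) <= tol:
            blocked.add(rid)
    return blocked


def brute_force_consistent(model, eps: float = 1e-4, open_exchange: bool = True) -> set[str]:
    """Flux-consistent reactions: those attaining |v| >= eps in some distribution."""
    S, lb, ub, rids = _naive_system(model)
    if open_exchange:
        exchange = {r.id for r in model.exchanges}
        for j, rid in enumerate(rids):
            if rid in exchange:
                lb[j] = min(lb[j], -1000.0)
    consistent = set()
    thr = 0.99 * eps
    for j, rid in enumerate(rids):
        vmax = _optimize_flux(S, lb, ub, j, "max")
        if vmax is not None and vmax >= thr:
            consistent.add(rid)
            continue
        vmin = _optimize_flux(S, lb, ub, j, "min")
        if vmin is not None and vmin <= -thr:
            consistent.add(rid)
    return consistent


def _subnetwork_consistent(S, lb, ub, rids, subset: set[str], eps: float) -> bool:
    """Every reaction of ``subset`` carries |v| >= eps with the rest closed."""
    lb2, ub2 = lb.copy(), ub.copy()
    for j, rid in enumerate(rids):
        if rid not in subset:
            lb2[j] = ub2[j] = 0.0
    thr = 0.99 * eps
    for j, rid in enumerate(rids):
        if rid not in subset:
            continue
        vmax = _optimize_flux(S, lb2, ub2, j, "max")
        if vmax is not None and vmax >= thr:
            continue
        vmin = _optimize_flux(S, lb2, ub2, j, "min")
        if vmin is None or vmin > -thr:
            return False
    return True


def brute_force_min_consistent_superset(model, core: set[str], eps: float = 1e-4) -> list[set[str]]:
    """All minimum-cardinality flux-consistent reaction sets containing ``core``.

    Enumerates supersets of the core in increasing size; guarded to
    networks of at most 14 reactions.
    """
    S, lb, ub, rids = _naive_system(model)
    others = [r for r in rids if r not in core]
    if len(rids) > 14:
        raise ValueError("oracle limited to networks of <= 14 reactions")
    for extra in range(len(others) + 1):
        hits = []
        for combo in itertools.combinations(others, extra):
            subset = set(core) | set(combo)
            if _subnetwork_consistent(S, lb, ub, rids, subset, eps):
                hits.append(subset)
        if hits:
            return hits
    return []


def brute_force_min_gapfill(
    model,
    kept: set[str],
    u: str,
    K: list[str],
    delta: float = 1e-3,
    medium_scenario: bool = False,
) -> list[set[str]]:
    """All minimum-cardinality subsets of ``K`` restoring flux >= delta through ``u``.

    Intracellular reading: reactions in ``K`` outside the chosen subset are
    closed, reactions in ``kept`` (and exchanges) keep their bounds.
    Medium reading (``medium_scenario``): ``K`` lists exchange reaction ids
    whose *uptake* is enabled by selection; unselected exchanges lose
    uptake, intracellular reactions outside ``kept`` are closed.
    Returns all minimal subsets (empty list: no gap fill exists).
    """
    if len(K) > 15:
        raise ValueError("oracle limited to |K| <= 15")
    S, lb, ub, rids = _naive_system(model)
    exchange = {r.id for r in model.exchanges}
    u_j = rids.index(u)

    def feasible(chosen: set[str]) -> bool:
        lb2, ub2 = lb.copy(), ub.copy()
        for j, rid in enumerate(rids):
            if medium_scenario:
                if rid in exchange:
                    if rid not in chosen:
                        lb2[j] = max(0.0, lb2[j])
                elif rid not in kept:
                    lb2[j] = ub2[j] = 0.0
            else:
                # missing intracellular reactions stay closed unless chosen;
                # exchanges keep their template bounds
                if rid not in kept and rid not in chosen and rid not in exchange:
                    lb2[j] = ub2[j] = 0.0
        vmax = _optimize_flux(S, lb2, ub2, u_j, "max")
        return vmax is not None and vmax >= delta

    for size in range(len(K) + 1):
        hits = [set(c) for c in itertools.combinations(K, size) if feasible(set(c))]
        if hits:
            return hits
    return []


def brute_force_tinit_objective(
    model,
    ras,
    protected: set[str],
    eps: float = 1e-4,
) -> tuple[float, list[set[str]]]:
    """Best achievable summed score over simultaneously-active subnetworks.

    Enumerates every reaction subset containing ``protected``; a subset is
    feasible when all its reactions carry |v| >= eps in one common flux
    distribution with the rest closed.  Direction choices for reversible
    members are enumerated exhaustively (guarded to <= 3 reversibles).
    Returns ``(best objective, argmax subsets)``.
    """
    S, lb, ub, rids = _naive_system(model)
    if len(rids) > 12:
        raise ValueError("oracle limited to networks of <= 12 reactions")
    reversible = [r for j, r in enumerate(rids) if lb[j] < 0]
    if len(reversible) > 3:
        raise ValueError("oracle limited to <= 3 reversible reactions")

    def feasible(subset: set[str]) -> bool:
        rev_members = [r for r in reversible if r in subset]
        for signs in itertools.product((1, -1), repeat=len(rev_members)):
            sign_of = dict(zip(rev_members, signs))
            lb2, ub2 = lb.copy(), ub.copy()
            ok = True
            for j, rid in enumerate(rids):
                if rid not in subset:
                    lb2[j] = ub2[j] = 0.0
                elif sign_of.get(rid, 1) > 0:
                    lb2[j] = max(lb2[j], eps)
                else:
                    ub2[j] = min(ub2[j], -eps)
                if lb2[j] > ub2[j]:
                    ok = False
                    break
            if not ok:
                continue
            res = linprog(
                np.zeros(len(rids)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(lb2, ub2)), method="highs",
            )
            if res.status == 0:
                return True
        return False

    others = [r for r in rids if r not in protected]
    best = -np.inf
    argmax: list[set[str]] = []
    for size in range(len(others) + 1):
        for combo in itertools.combinations(others, size):
            subset = set(protected) | set(combo)
            score = float(sum(ras.get(r, 0.0) for r in subset))
            if score < best - 1e-12:
                continue
            if not feasible(subset):
                continue
            if score > best + 1e-12:
                best = score
                argmax = [subset]
            else:
                argmax.append(subset)
    return best, argmax
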