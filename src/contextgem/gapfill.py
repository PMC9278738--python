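"""Minimal-cardinality gap filling of context-specific models (MILP).

After extraction, a context model can fail its growth check.  Gap filling
finds the smallest set of candidate reactions whose re-activation restores
steady-state flux through a required objective reaction ``u`` (usually
biomass).  The network is first split so every flux is non-negative; each
candidate ``k`` then gets a binary indicator ``y_k`` coupled to its flux by
a big-M constraint (``M * y_k - v_k >= 0``: any flux forces the indicator
on), and the MILP minimises ``sum(y_k)`` subject to ``S.v = 0`` and
``v_u >= delta``, the activation threshold standing in for "non-zero flux".

Two scenarios are supported:

* ``intracellular`` — candidates are the intracellular reactions missing
  from the presence vector ``r`` (exchanges are excluded from the candidate
  set); the solution is the smallest set of missing internal reactions to
  re-insert.
* ``medium`` — the internal reaction content of ``r`` is fixed (missing
  internal reactions stay disabled); exchanges are split into secretion and
  uptake halves and the candidates are the uptake halves, so the solution
  is a minimal growth medium.

Optimal solutions can be enumerated in order of cardinality via integer
cuts, mirroring k-shortest elementary-flux-mode style enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from . import core as mc
from .reconstruction import ReactionPresence

__all__ = [
    "GapfillProblem",
    "GapfillSolution",
    "build_gapfill_problem",
    "efm_gapfill",
    "enumerate_gapfill_solutions",
]

DEFAULT_BIG_M = 1e6
#: Fraction of u's upper bound used as the "non-zero flux" activation threshold.
DEFAULT_ACTIVATION_FRACTION = 1e-4


@dataclass
class GapfillProblem:
    """A fully split gap-filling MILP instance.

    ``candidates`` maps each selectable unit (an original reaction in the
    intracellular scenario; a single uptake half in the medium scenario) to
    the split-network column indices its indicator controls.
    """

    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    reaction_ids: list[str]
    candidates: dict[str, list[int]]
    objective_reaction: str
    objective_columns: list[int]
    activation_threshold: float
    big_m: float
    scenario: str


@dataclass
class GapfillSolution:
    """Result of one gap-filling solve."""

    selected: list[str]
    status: str  # "optimal" | "no_gapfill" | "timeout"
    witness: pd.Series | None = None

    @property
    def cardinality(self) -> int:
        return len(self.selected)

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


def build_gapfill_problem(
    model,
    r: ReactionPresence,
    u: str,
    scenario: str = "intracellular",
    big_m: float = DEFAULT_BIG_M,
    activation_fraction: float = DEFAULT_ACTIVATION_FRACTION,
    zero_absent_exchanges: bool = False,
) -> GapfillProblem:
    """Assemble the split network, candidate set and thresholds of the MILP.

    ``zero_absent_exchanges`` (intracellular scenario only) additionally
    disables exchanges missing from ``r``; by default they keep their
    template bounds.
    """
    if scenario not in ("intracellular", "medium"):
        raise ValueError(f"scenario must be 'intracellular' or 'medium', got {scenario!r}")
    if u not in {x.id for x in model.reactions}:
        raise ValueError(f"objective reaction {u!r} not in model")

    exchange_ids = {x.id for x in model.exchanges}
    split = mc.split_reversible(model)
    arrays = mc.network_arrays(split.model)
    sidx = {rid: j for j, rid in enumerate(arrays.reaction_ids)}
    lb = arrays.lower_bounds.copy()
    ub = np.where(np.isposinf(arrays.upper_bounds), big_m, arrays.upper_bounds)
    removed = r.removed

    def cols(rid: str) -> list[int]:
        fwd, rev = split.pairs[rid]
        return [sidx[fwd]] + ([sidx[rev]] if rev is not None else [])

    candidates: dict[str, list[int]] = {}
    if scenario == "intracellular":
        for rid in sorted(removed):
            if rid in exchange_ids:
                if zero_absent_exchanges:
                    for c in cols(rid):
                        ub[c] = 0.0
            else:
                candidates[rid] = cols(rid)
    else:  # medium
        for rid in sorted(removed):
            if rid not in exchange_ids:
                for c in cols(rid):
                    ub[c] = 0.0
        for rid in sorted(exchange_ids):
            fwd, rev = split.pairs[rid]
            if rev is not None:  # the uptake-direction half
                candidates[f"{rid}:uptake"] = [sidx[rev]]

    ub_u = max(x for x in (model.reactions.get_by_id(u).upper_bound, 1.0) if np.isfinite(x))
    delta = activation_fraction * ub_u
    eff_m = max(big_m, float(ub.max()) if len(ub) else big_m)
    return GapfillProblem(
        S=arrays.S,
        lower_bounds=lb,
        upper_bounds=ub,
        reaction_ids=arrays.reaction_ids,
        candidates=candidates,
        objective_reaction=u,
        objective_columns=cols(u),
        activation_threshold=delta,
        big_m=eff_m,
        scenario=scenario,
    )


def _solve(problem: GapfillProblem, extra_cuts: list[set[str]], couple_lower: bool):
    m, n = problem.S.shape
    cand_ids = sorted(problem.candidates)
    nk = len(cand_ids)
    nvar = n + nk

    lb = problem.lower_bounds.copy()
    ub = problem.upper_bounds.copy()
    # the objective reaction must carry flux: forward half >= delta
    u_col = problem.objective_columns[0]
    lb[u_col] = max(lb[u_col], problem.activation_threshold)

    constraints = [LinearConstraint(np.hstack([problem.S, np.zeros((m, nk))]), 0.0, 0.0)]
    rows, lo, hi = [], [], []
    for k, cid in enumerate(cand_ids):
        for c in problem.candidates[cid]:
            row = np.zeros(nvar)  # M*y_k - v_c >= 0, with M tightened to the column bound
            row[c] = -1.0
            row[n + k] = min(problem.big_m, ub[c]) if ub[c] > 0 else problem.big_m
            rows.append(row)
            lo.append(0.0)
            hi.append(np.inf)
        if couple_lower:
            row = np.zeros(nvar)  # sum(v_c) - delta*y_k >= 0
            for c in problem.candidates[cid]:
                row[c] = 1.0
            row[n + k] = -problem.activation_threshold
            rows.append(row)
            lo.append(0.0)
            hi.append(np.inf)
    if rows:
        constraints.append(LinearConstraint(np.array(rows), np.array(lo), np.array(hi)))
    for cut in extra_cuts:  # integer cut: sum of y over a previous solution <= |sol|-1
        row = np.zeros(nvar)
        for cid in cut:
            row[n + cand_ids.index(cid)] = 1.0
        constraints.append(LinearConstraint(row, -np.inf, len(cut) - 1))

    c_obj = np.concatenate([np.zeros(n), np.ones(nk)])
    integrality = np.concatenate([np.zeros(n), np.ones(nk)])
    var_lb = np.concatenate([lb, np.zeros(nk)])
    var_ub = np.concatenate([ub, np.ones(nk)])
    res = milp(
        c=c_obj,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"mip_rel_gap": 1e-9},
    )
    if res.status == 1:
        return GapfillSolution(selected=[], status="timeout")
    if res.status != 0 or res.x is None:
        return GapfillSolution(selected=[], status="no_gapfill")
    y = res.x[n:]
    selected = [cid for k, cid in enumerate(cand_ids) if y[k] > 0.5]
    witness = pd.Series(res.x[:n], index=problem.reaction_ids)
    return GapfillSolution(selected=selected, status="optimal", witness=witness)


def efm_gapfill(problem: GapfillProblem, couple_lower: bool = False) -> GapfillSolution:
    """Solve the gap-filling MILP to a minimum-cardinality solution.

    With no candidates and a feasible base problem the empty solution is
    returned; an infeasible MILP reports ``no_gapfill`` (distinct from a
    solver failure, which raises).
    """
    return _solve(problem, extra_cuts=[], couple_lower=couple_lower)


def enumerate_gapfill_solutions(
    problem: GapfillProblem, k: int, couple_lower: bool = False
) -> list[GapfillSolution]:
    """Up to ``k`` distinct solutions in non-decreasing cardinality.

    Each found solution is excluded from subsequent solves by an integer
    cut, in the spirit of k-shortest elementary-flux-mode enumeration.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cuts: list[set[str]] = []
    out: list[GapfillSolution] = []
    for _ in range(k):
        sol = _solve(problem, extra_cuts=cuts, couple_lower=couple_lower)
        if not sol.feasible:
            break
        out.append(sol)
        if not sol.selected:  # the empty solution admits no nonempty cut
            break
        cuts.append(set(sol.selected))
    return out


def apply_gapfill(model, r: ReactionPresence, solution: GapfillSolution) -> ReactionPresence:
    """Merge a gap-fill solution back into a presence vector.

    Medium-scenario selections (uptake halves, ``rid:uptake``) re-enable the
    corresponding exchange reaction.
    """
    kept = r.kept
    for cid in solution.selected:
        kept.add(cid.split(":")[0])
    return ReactionPresence.from_kept(model, kept, provenance=r.provenance + "+gapfill")
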