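"""Context-specific model extraction: FASTCORE, tINIT and the parameter grid.

Both extraction algorithms take the (consistent) template model plus
expression-derived reaction scores and return a binary presence vector
``r`` over the template's reactions:

* **FASTCORE** takes a *core* set of reactions that must be kept (here:
  reactions with strictly positive activity score) and finds an
  approximately minimal flux-consistent subnetwork containing it, by
  alternating two LPs: LP7 maximises the number of core reactions carrying
  at least ``eps`` flux, LP10 minimises the L1 flux through non-core
  reactions while the found core subset stays active.
* **tINIT** solves a MILP over reaction inclusion indicators, maximising
  the summed activity scores of included reactions (negative scores act as
  removal incentives) subject to every included reaction carrying at least
  ``eps`` flux in one common steady-state flux distribution, with protected
  reactions (the biomass pseudo-reaction) forced in.

Reactions flagged absent are knocked out by zeroing their bounds rather
than deleted, so downstream gap filling can re-enable them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, linprog, milp

from . import core as mc

__all__ = [
    "ReactionPresence",
    "ReconstructionConfig",
    "fastcc",
    "fastcore",
    "tinit",
    "apply_presence",
    "check_model",
    "parameter_grid",
    "TABLE_OPTIONS",
]

DEFAULT_EPS = 1e-4
_SUPPORT_FRACTION = 0.99  # flux counts as active above this fraction of eps


@dataclass
class ReactionPresence:
    """Binary keep/remove vector aligned to the template model's reactions."""

    presence: pd.Series  # int 0/1 indexed by reaction id
    provenance: str = ""

    def __post_init__(self):
        vals = set(self.presence.unique())
        if not vals <= {0, 1}:
            raise ValueError(f"presence entries must be 0/1, got {sorted(vals)}")

    @classmethod
    def from_kept(cls, model, kept: set[str], provenance: str = "") -> "ReactionPresence":
        ids = [r.id for r in model.reactions]
        return cls(pd.Series([1 if r in kept else 0 for r in ids], index=ids, dtype=int), provenance)

    @property
    def kept(self) -> set[str]:
        return set(self.presence.index[self.presence == 1])

    @property
    def removed(self) -> set[str]:
        return set(self.presence.index[self.presence == 0])

    def to_tsv(self, path: str) -> None:
        self.presence.rename("present").to_csv(path, sep="\t", header=True)


# ---------------------------------------------------------------------------
# LP helpers (scipy / HiGHS)
# ---------------------------------------------------------------------------

def _finite_bounds(lb, ub, cap=1e4):
    lb = np.where(np.isneginf(lb), -cap, lb)
    ub = np.where(np.isposinf(ub), cap, ub)
    return lb.astype(float), ub.astype(float)


def _lp7(S, lb, ub, J, eps):
    """Maximise the number of reactions in J carrying >= eps forward flux.

    Variables [v, z] with z_j in [0, eps] and v_j >= z_j for j in J;
    maximise sum(z).  Returns the optimal v or None when infeasible.
    """
    m, n = S.shape
    nj = len(J)
    c = np.concatenate([np.zeros(n), -np.ones(nj)])
    A_eq = np.hstack([S, np.zeros((m, nj))])
    # z_j - v_j <= 0
    A_ub = np.zeros((nj, n + nj))
    for row, j in enumerate(J):
        A_ub[row, j] = -1.0
        A_ub[row, n + row] = 1.0
    bounds = list(zip(lb, ub)) + [(0.0, eps)] * nj
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(nj), A_eq=A_eq, b_eq=np.zeros(m), bounds=bounds, method="highs")
    return res.x[:n] if res.status == 0 else None


def _lp10(S, lb, ub, K, P, eps):
    """Minimise L1 flux through P while every reaction in K carries >= eps.

    Variables [v, zeta_P]; minimise sum(zeta) with -zeta_p <= v_p <= zeta_p.
    Returns optimal v or None when infeasible.
    """
    m, n = S.shape
    np_ = len(P)
    c = np.concatenate([np.zeros(n), np.ones(np_)])
    A_eq = np.hstack([S, np.zeros((m, np_))])
    rows = []
    for row, p in enumerate(P):
        r1 = np.zeros(n + np_)
        r1[p] = 1.0
        r1[n + row] = -1.0  # v_p - zeta_p <= 0
        r2 = np.zeros(n + np_)
        r2[p] = -1.0
        r2[n + row] = -1.0  # -v_p - zeta_p <= 0
        rows.extend([r1, r2])
    A_ub = np.array(rows) if rows else None
    b_ub = np.zeros(2 * np_) if rows else None
    lb2 = lb.copy()
    for k in K:
        lb2[k] = max(lb2[k], eps)
    bounds = list(zip(lb2, ub)) + [(0.0, None)] * np_
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(m), bounds=bounds, method="highs")
    return res.x[:n] if res.status == 0 else None


# ---------------------------------------------------------------------------
# fastcc
# ---------------------------------------------------------------------------

def fastcc(model, eps: float = DEFAULT_EPS, open_exchange: bool = True) -> set[str]:
    """Maximal flux-consistent subnetwork under open exchange conditions.

    A reaction is consistent when it attains |v| >= eps in some admissible
    steady-state distribution.  A block LP7 pass resolves most reactions at
    once; the remainder are settled by per-reaction maximisation and
    minimisation.  Equals the complement of the blocked set up to the eps
    activation semantics.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    work = mc.open_exchanges(model) if open_exchange else model
    arrays = mc.network_arrays(work)
    S = arrays.S
    lb, ub = _finite_bounds(arrays.lower_bounds, arrays.upper_bounds)
    n = arrays.n_reactions
    thr = _SUPPORT_FRACTION * eps

    consistent: set[int] = set()
    # block pass, forward direction
    v = _lp7(S, lb, ub, list(range(n)), eps)
    if v is None:
        raise RuntimeError("base model is infeasible at steady state")
    consistent |= {j for j in range(n) if abs(v[j]) >= thr}
    # block pass, reverse direction for unresolved reversibles
    rev = [j for j in range(n) if j not in consistent and lb[j] < 0]
    if rev:
        Sf = S.copy()
        lbf, ubf = lb.copy(), ub.copy()
        for j in rev:
            Sf[:, j] *= -1.0
            lbf[j], ubf[j] = -ub[j], -lb[j]
        v = _lp7(Sf, lbf, ubf, rev, eps)
        if v is not None:
            consistent |= {j for j in range(n) if abs(v[j]) >= thr}
    # per-reaction cleanup
    for j in range(n):
        if j in consistent:
            continue
        c = np.zeros(n)
        c[j] = -1.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
        if res.status == 0 and res.x[j] >= thr:
            consistent.add(j)
            continue
        if lb[j] < 0:
            res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
            if res.status == 0 and res.x[j] <= -thr:
                consistent.add(j)
    return {arrays.reaction_ids[j] for j in consistent}


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

def _find_sparse_mode(S, lb, ub, J, P, eps):
    """One FASTCORE iteration: activate some of J, sparsify over P."""
    if not J:
        return set()
    v = _lp7(S, lb, ub, sorted(J), eps)
    if v is None:
        return set()
    thr = _SUPPORT_FRACTION * eps
    K = {j for j in J if v[j] >= thr}
    if not K:
        return set()
    v = _lp10(S, lb, ub, sorted(K), sorted(P), eps)
    if v is None:
        return set()
    support_tol = max(1e-9, 1e-6 * eps)
    return {j for j in range(S.shape[1]) if abs(v[j]) > support_tol}


def fastcore(model, core: set[str], eps: float = DEFAULT_EPS) -> ReactionPresence:
    """FASTCORE extraction: a compact flux-consistent subnetwork covering ``core``.

    Core reactions outside the model's consistent part are dropped with a
    warning; an empty effective core is an error.  The returned presence
    vector always contains the effective core and induces a flux-consistent
    subnetwork (approximately minimal; no global optimality guarantee).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    consistent_ids = fastcc(model, eps=eps, open_exchange=False)
    effective = set(core) & consistent_ids
    dropped = set(core) - effective
    if dropped:
        warnings.warn(f"dropping {len(dropped)} inconsistent core reactions: {sorted(dropped)[:5]}")
    if not effective:
        raise ValueError("effective core is empty after dropping inconsistent reactions")

    arrays = mc.network_arrays(model)
    idx = {rid: j for j, rid in enumerate(arrays.reaction_ids)}
    S = arrays.S.copy()
    lb, ub = _finite_bounds(arrays.lower_bounds, arrays.upper_bounds)
    C = {idx[r] for r in effective}
    irreversible = {j for j in range(arrays.n_reactions) if lb[j] >= 0}

    J = C & irreversible
    P = set(range(arrays.n_reactions)) - C
    A = _find_sparse_mode(S, lb, ub, J, P, eps)
    J = C - A
    flipped = False
    singleton = False
    guard = 0
    while J:
        guard += 1
        if guard > 4 * arrays.n_reactions:
            raise RuntimeError("FASTCORE failed to converge")
        P = set(range(arrays.n_reactions)) - C - A
        target = {min(J)} if singleton else J
        A |= _find_sparse_mode(S, lb, ub, target, P, eps)
        if J & A:
            J -= A
            flipped = False
            singleton = False
        else:
            flippable = {j for j in target if j not in irreversible}
            if flipped or not flippable:
                if singleton:
                    raise RuntimeError(
                        f"cannot activate core reaction(s) {sorted(arrays.reaction_ids[j] for j in target)}"
                    )
                flipped = False
                singleton = True
            else:
                for j in flippable:
                    S[:, j] *= -1.0
                    lb[j], ub[j] = -ub[j], -lb[j]
                flipped = True
    kept = {arrays.reaction_ids[j] for j in A} | effective
    return ReactionPresence.from_kept(model, kept, provenance=f"FASTCORE(eps={eps})")


# ---------------------------------------------------------------------------
# tINIT
# ---------------------------------------------------------------------------

def tinit(
    model,
    ras: pd.Series,
    protected: set[str],
    eps: float = DEFAULT_EPS,
    mip_gap: float = 1e-6,
) -> ReactionPresence:
    """tINIT extraction: maximise summed activity scores of included reactions.

    Reaction-level MILP on the split (irreversible) network: inclusion
    indicator ``y_j`` per original reaction; ``y_j = 1`` requires the
    reaction to carry at least ``eps`` flux (in either direction) in the one
    steady-state flux distribution the MILP also solves for, and ``y_j = 0``
    forces zero flux.  Protected reactions (at minimum the biomass
    objective) have ``y`` fixed to 1.  Negative scores penalise inclusion.
    """
    split = mc.split_reversible(model)
    arrays = mc.network_arrays(split.model)
    sidx = {rid: j for j, rid in enumerate(arrays.reaction_ids)}
    lb, ub = _finite_bounds(arrays.lower_bounds, arrays.upper_bounds)
    orig_ids = [r.id for r in model.reactions]
    missing = set(protected) - set(orig_ids)
    if missing:
        raise ValueError(f"protected reactions not in model: {sorted(missing)}")

    n_s = arrays.n_reactions
    n_o = len(orig_ids)
    m = arrays.n_metabolites
    nvar = n_s + n_o
    w = ras.reindex(orig_ids).fillna(0.0).to_numpy()

    # feasibility pre-check: every protected reaction active in the full model
    for p in protected:
        fwd, rev = split.pairs[p]
        c = np.zeros(n_s)
        c[sidx[fwd]] = -1.0
        if rev is not None:
            c[sidx[rev]] = -1.0
        res = linprog(c, A_eq=arrays.S, b_eq=np.zeros(m), bounds=list(zip(lb, ub)), method="highs")
        if res.status != 0 or -res.fun < eps:
            raise ValueError(f"protected reaction {p!r} cannot carry flux in the template model")

    constraints = [LinearConstraint(np.hstack([arrays.S, np.zeros((m, n_o))]), 0.0, 0.0)]
    rows, lo, hi = [], [], []
    for k, rid in enumerate(orig_ids):
        fwd, rev = split.pairs[rid]
        cols = [sidx[fwd]] + ([sidx[rev]] if rev is not None else [])
        for c_ in cols:  # v_c - ub_c * y_k <= 0
            row = np.zeros(nvar)
            row[c_] = 1.0
            row[n_s + k] = -ub[c_] if ub[c_] > 0 else -1.0
            rows.append(row)
            lo.append(-np.inf)
            hi.append(0.0)
        row = np.zeros(nvar)  # sum(v_c) - eps * y_k >= 0
        for c_ in cols:
            row[c_] = 1.0
        row[n_s + k] = -eps
        rows.append(row)
        lo.append(0.0)
        hi.append(np.inf)
    constraints.append(LinearConstraint(np.array(rows), np.array(lo), np.array(hi)))

    var_lb = np.concatenate([lb, np.zeros(n_o)])
    var_ub = np.concatenate([ub, np.ones(n_o)])
    for p in protected:
        var_lb[n_s + orig_ids.index(p)] = 1.0
    c_obj = np.concatenate([np.zeros(n_s), -w])
    integrality = np.concatenate([np.zeros(n_s), np.ones(n_o)])
    from scipy.optimize import Bounds

    res = milp(
        c=c_obj,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"mip_rel_gap": mip_gap},
    )
    if res.status != 0:
        raise RuntimeError(f"tINIT MILP did not solve: {res.message}")
    y = res.x[n_s:]
    kept = {rid for k, rid in enumerate(orig_ids) if y[k] > 0.5}
    rp = ReactionPresence.from_kept(model, kept, provenance=f"tINIT(eps={eps})")
    rp.objective_value = float(-res.fun)
    return rp


def tinit_objective(presence: ReactionPresence, ras: pd.Series) -> float:
    """Σ scores of included reactions — the quantity tINIT maximises."""
    kept = presence.presence == 1
    return float(ras.reindex(presence.presence.index).fillna(0.0)[kept].sum())


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def apply_presence(model, presence: ReactionPresence):
    """Knock out absent reactions (bounds to 0,0) without deleting them."""
    model = model.copy()
    for rid in presence.removed:
        model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    return model


def check_model(
    context_model,
    medium: set[str] | None = None,
    growth_tol: float = 1e-6,
    objective: str | None = None,
) -> dict:
    """Post-extraction sanity checks on a context-specific model.

    ``grows``: biomass FBA optimum exceeds the growth tolerance under the
    model's current exchange bounds.  ``grows_on_medium``: same after
    restricting uptake to the supplied medium metabolites (None when no
    medium is given).  Infeasible counts as not growing.
    """
    sol = mc.fba(context_model, objective=objective)
    grows = sol.feasible and sol.objective_value > growth_tol
    grows_on_medium = None
    if medium is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            constrained = mc.apply_medium(context_model, medium)
        msol = mc.fba(constrained, objective=objective)
        grows_on_medium = msol.feasible and msol.objective_value > growth_tol
    return {"grows": bool(grows), "grows_on_medium": grows_on_medium}


# ---------------------------------------------------------------------------
# Parameter grid
# ---------------------------------------------------------------------------

TABLE_OPTIONS = {
    "algorithm": ("FASTCORE", "tINIT"),
    "p_gmin": (10, 25, 50, 75, 90),
    "p_gmax": (25, 50, 75, 90),
    "p_local": (10, 25, 50, 75, 90),
    "strategy": ("global", "localT1", "localT2"),
    "or_fn": ("max", "sum"),
    "and_fn": ("min",),
}


@dataclass(frozen=True)
class ReconstructionConfig:
    """One cell of the reconstruction parameter grid."""

    algorithm: str
    strategy: str
    p_gmax: int
    p_gmin: int | None = None
    p_local: int | None = None
    or_fn: str = "max"
    and_fn: str = "min"

    def __post_init__(self):
        if self.strategy == "localT2":
            if self.p_gmin is None or self.p_local is None:
                raise ValueError("localT2 requires p_gmin and p_local")
            if self.p_gmin >= self.p_gmax:
                raise ValueError("localT2 requires p_gmin < p_gmax")
        elif self.strategy == "localT1":
            if self.p_local is None:
                raise ValueError("localT1 requires p_local")
            if self.p_gmin is not None:
                raise ValueError("localT1 does not use p_gmin")
        elif self.strategy == "global":
            if self.p_gmin is not None or self.p_local is not None:
                raise ValueError("global strategy uses only p_gmax")
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def label(self) -> str:
        parts = [self.algorithm, self.strategy, f"gmax{self.p_gmax}"]
        if self.p_gmin is not None:
            parts.append(f"gmin{self.p_gmin}")
        if self.p_local is not None:
            parts.append(f"local{self.p_local}")
        parts.append(self.or_fn)
        return "_".join(parts)


def parameter_grid(options: dict | None = None) -> list[ReconstructionConfig]:
    """Enumerate every valid parameter combination, deterministically ordered.

    The Cartesian product of the option table is filtered by a validity
    predicate: percentiles a strategy does not use are dropped (so no
    duplicate configurations are emitted) and localT2 requires
    ``p_gmin < p_gmax``.
    """
    opts = dict(TABLE_OPTIONS)
    if options:
        opts.update(options)
    seen = set()
    grid = []
    for algo, strat, p_gmax, p_gmin, p_local, or_fn, and_fn in itertools.product(
        opts["algorithm"], opts["strategy"], opts["p_gmax"], opts["p_gmin"],
        opts["p_local"], opts["or_fn"], opts["and_fn"],
    ):
        if strat == "global":
            p_gmin, p_local = None, None
        elif strat == "localT1":
            p_gmin = None
        elif strat == "localT2" and p_gmin >= p_gmax:
            continue
        key = (algo, strat, p_gmax, p_gmin, p_local, or_fn, and_fn)
        if key in seen:
            continue
        seen.add(key)
        grid.append(
            ReconstructionConfig(
                algorithm=algo, strategy=strat, p_gmax=p_gmax, p_gmin=p_gmin,
                p_local=p_local, or_fn=or_fn, and_fn=and_fn,
            )
        )
    return grid
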