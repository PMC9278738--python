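"""Constraint-based model handling: SBML I/O, preprocessing and simulation.

The package uses :class:`cobra.Model` as its in-memory representation of a
genome-scale metabolic model (GSMM): stoichiometry ``S``, flux bounds,
gene-protein-reaction (GPR) rules and the biomass objective.  This module
wraps the handful of standard constraint-based operations the pipeline
needs — flux balance analysis (FBA), its parsimonious variant (pFBA), flux
variability analysis (FVA), blocked-reaction detection, medium constraints
and reversible-reaction splitting — behind a small functional surface with
explicit tolerances, and adds plain-array views of the network used by the
bespoke LP/MILP algorithms elsewhere in the package.

Conventions
-----------
* Exchange reactions follow the COBRA sign convention: negative flux is
  uptake, positive flux is secretion.
* "Open exchange conditions" means every exchange reaction is allowed to
  take up its metabolite at a configurable magnitude (default 1000).
* Steady state is enforced to ``STEADY_STATE_TOL`` (default 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import cobra.io
import numpy as np
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "STEADY_STATE_TOL",
    "OPEN_EXCHANGE_BOUND",
    "FluxDistribution",
    "NetworkArrays",
    "SplitModel",
    "read_sbml",
    "write_sbml",
    "boundary_metabolites",
    "remove_boundary_metabolites",
    "open_exchanges",
    "fba",
    "pfba",
    "fva",
    "find_blocked_reactions",
    "apply_medium",
    "split_reversible",
    "network_arrays",
]

#: Maximum allowed |S.v| residual for a flux distribution to count as steady state.
STEADY_STATE_TOL = 1e-6

#: Uptake magnitude used when opening exchange reactions for FVA/consistency.
OPEN_EXCHANGE_BOUND = 1000.0


@dataclass
class FluxDistribution:
    """A solved flux state of a model.

    Attributes
    ----------
    fluxes : pandas.Series
        Flux per reaction, indexed by reaction id, in model units
        (mmol/gDW/h for genome-scale models; arbitrary units in fixtures).
    objective_value : float
        Flux through the objective reaction (NaN when infeasible).
    status : str
        Solver status, ``"optimal"`` or ``"infeasible"``.
    """

    fluxes: pd.Series
    objective_value: float
    status: str

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


@dataclass
class NetworkArrays:
    """Plain-array view of a model used by the in-house LP/MILP builders."""

    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    def index_of(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)


@dataclass
class SplitModel:
    """An irreversible ("split") version of a model.

    Every reaction with a negative lower bound is replaced by a forward and
    a mirrored reverse reaction, both with non-negative bounds.  ``pairs``
    maps each original reaction id to its ``(forward_id, reverse_id)`` pair;
    ``reverse_id`` is ``None`` for reactions that were already irreversible.
    A split flux vector maps back to the original space as
    ``v_orig = v_forward - v_reverse``.
    """

    model: cobra.Model
    pairs: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def recombine(self, split_fluxes: pd.Series) -> pd.Series:
        """Map a flux vector of the split model back to the original reactions."""
        out = {}
        for rid, (fwd, rev) in self.pairs.items():
            v = float(split_fluxes[fwd])
            if rev is not None:
                v -= float(split_fluxes[rev])
            out[rid] = v
        return pd.Series(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sbml(path: str) -> cobra.Model:
    """Read an SBML (Level 3 + fbc) model.

    Raises
    ------
    cobra.io.sbml.CobraSBMLError
        If the file is malformed.
    ValueError
        If the model declares no objective reaction.
    """
    model = cobra.io.read_sbml_model(str(path))
    if not _objective_ids(model):
        raise ValueError(f"model {model.id!r} has no objective reaction configured")
    return model


def write_sbml(model: cobra.Model, path: str) -> None:
    cobra.io.write_sbml_model(model, str(path))


def _objective_ids(model: cobra.Model) -> list[str]:
    from cobra.util.solver import linear_reaction_coefficients

    return [r.id for r in linear_reaction_coefficients(model)]


def objective_id(model: cobra.Model) -> str:
    ids = _objective_ids(model)
    if not ids:
        raise ValueError("model has no objective reaction")
    return ids[0]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def boundary_metabolites(
    model: cobra.Model,
    boundary_compartments: set[str] = frozenset({"b"}),
    suffix: str = "_b",
) -> list[str]:
    """Identify boundary species by compartment or id-suffix convention.

    SBML ``boundaryCondition`` flags are not retained by the reader, so the
    widely used convention of a dedicated boundary compartment (``b``) or a
    ``_b`` id suffix is applied instead; both are configurable.
    """
    found = []
    for met in model.metabolites:
        if met.compartment in boundary_compartments or met.id.endswith(suffix):
            found.append(met.id)
    return found


def remove_boundary_metabolites(
    model: cobra.Model,
    metabolite_ids: list[str] | None = None,
    **detect_kwargs,
) -> cobra.Model:
    """Strip boundary species (rows of S), keeping every reaction.

    Boundary metabolites are placeholders added to mass-balance exchange
    reactions; removing their rows makes those exchanges single-sided, which
    is the form every downstream LP expects.  Returns a modified copy; a
    model without boundary species is returned unchanged (still a copy).
    """
    model = model.copy()
    ids = metabolite_ids if metabolite_ids is not None else boundary_metabolites(model, **detect_kwargs)
    for mid in ids:
        met = model.metabolites.get_by_id(mid)
        for rxn in list(met.reactions):
            rxn.subtract_metabolites({met: rxn.metabolites[met]})
        model.remove_metabolites([met])
    return model


def open_exchanges(model: cobra.Model, bound: float = OPEN_EXCHANGE_BOUND) -> cobra.Model:
    """Return a copy with every exchange allowed to take up at magnitude ``bound``."""
    model = model.copy()
    for rxn in model.exchanges:
        rxn.lower_bound = min(rxn.lower_bound, -abs(bound))
    return model


def apply_medium(model: cobra.Model, medium_metabolites: set[str]) -> cobra.Model:
    """Restrict uptake to a set of medium metabolites.

    Every exchange reaction whose metabolite is not in the medium gets its
    lower bound raised to ``max(0, lb)``, i.e. secretion stays possible but
    uptake is forbidden.  Medium entries may be metabolite ids or exchange
    reaction ids.  Entries matching nothing produce a warning (media lists
    are often partial), not an error.
    """
    import warnings

    model = model.copy()
    medium = set(medium_metabolites)
    matched: set[str] = set()
    for rxn in model.exchanges:
        met_ids = {m.id for m in rxn.metabolites}
        hit = (rxn.id in medium) or (met_ids & medium)
        if hit:
            matched |= ({rxn.id} & medium) | (met_ids & medium)
        else:
            rxn.lower_bound = max(0.0, rxn.lower_bound)
    missing = medium - matched
    if missing:
        warnings.warn(f"medium entries not found in any exchange: {sorted(missing)}")
    return model


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def fba(
    model: cobra.Model,
    objective: str | None = None,
    sense: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimise one reaction's flux subject to S.v = 0."""
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    with model:
        if objective is not None:
            model.objective = model.reactions.get_by_id(objective)
        model.objective_direction = "max" if sense == "max" else "min"
        sol = model.optimize()
        if sol.status != "optimal":
            return FluxDistribution(
                fluxes=pd.Series(np.nan, index=[r.id for r in model.reactions]),
                objective_value=float("nan"),
                status="infeasible",
            )
        return FluxDistribution(sol.fluxes, float(sol.objective_value), "optimal")


def pfba(model: cobra.Model, objective: str | None = None) -> FluxDistribution:
    """Parsimonious FBA: among FBA optima, minimise total flux Σ|v_j|.

    Two-stage LP: the objective is fixed at its FBA optimum (fraction of
    optimum 1.0), then Σ|v| is minimised on the internally split model so
    the objective is linear.
    """
    from cobra.flux_analysis import pfba as _cobra_pfba
    from cobra.exceptions import Infeasible

    with model:
        if objective is not None:
            model.objective = model.reactions.get_by_id(objective)
        try:
            sol = _cobra_pfba(model, fraction_of_optimum=1.0)
        except Infeasible:
            return FluxDistribution(
                fluxes=pd.Series(np.nan, index=[r.id for r in model.reactions]),
                objective_value=float("nan"),
                status="infeasible",
            )
        obj = objective or objective_id(model)
        return FluxDistribution(sol.fluxes, float(sol.fluxes[obj]), "optimal")


def fva(
    model: cobra.Model,
    reactions: list[str] | None = None,
    open_exchange: bool = False,
    open_bound: float = OPEN_EXCHANGE_BOUND,
) -> pd.DataFrame:
    """Flux variability analysis: per-reaction (min, max) attainable flux.

    The optimum constraint is relaxed entirely (fraction of optimum 0), so
    the returned ranges describe the whole admissible flux space.
    """
    from cobra.util.solver import set_objective

    work = open_exchanges(model, open_bound) if open_exchange else model.copy()
    rxns = reactions if reactions is not None else [r.id for r in work.reactions]
    # drop the objective entirely: even fraction_of_optimum=0 would impose
    # objective >= 0, which clips reversible objective reactions
    set_objective(work, {})
    return flux_variability_analysis(work, reaction_list=rxns, fraction_of_optimum=0.0)


def find_blocked_reactions(
    model: cobra.Model,
    tol: float = STEADY_STATE_TOL,
    open_exchange: bool = True,
    open_bound: float = OPEN_EXCHANGE_BOUND,
) -> set[str]:
    """Reactions whose minimum and maximum flux are both null under open exchanges."""
    ranges = fva(model, open_exchange=open_exchange, open_bound=open_bound)
    blocked = ranges[(ranges["minimum"].abs() <= tol) & (ranges["maximum"].abs() <= tol)]
    return set(blocked.index)


def remove_blocked_reactions(
    model: cobra.Model, tol: float = STEADY_STATE_TOL
) -> tuple[cobra.Model, set[str]]:
    """Consistency step: drop blocked reactions; returns (model copy, removed ids)."""
    blocked = find_blocked_reactions(model, tol=tol)
    model = model.copy()
    model.remove_reactions([model.reactions.get_by_id(r) for r in blocked])
    return model, blocked


# ---------------------------------------------------------------------------
# Splitting and array extraction
# ---------------------------------------------------------------------------

def split_reversible(model: cobra.Model, suffix_fwd: str = "", suffix_rev: str = "__rev") -> SplitModel:
    """Split every reversible reaction into an irreversible forward/reverse pair.

    Needed wherever an LP requires all fluxes non-negative (pFBA's L1 term,
    the gap-filling MILP, medium-scenario exchange halves).
    """
    split = model.copy()
    pairs: dict[str, tuple[str, str | None]] = {}
    new_reactions = []
    for rxn in split.reactions:
        fwd_id = rxn.id + suffix_fwd
        if rxn.lower_bound < 0:
            rev = cobra.Reaction(rxn.id + suffix_rev)
            rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
            rev.bounds = (0.0, -rxn.lower_bound)
            rev.gene_reaction_rule = rxn.gene_reaction_rule
            new_reactions.append(rev)
            rxn.lower_bound = 0.0
            pairs[rxn.id] = (fwd_id, rev.id)
        else:
            pairs[rxn.id] = (fwd_id, None)
    split.add_reactions(new_reactions)
    return SplitModel(model=split, pairs=pairs)


def network_arrays(model: cobra.Model) -> NetworkArrays:
    """Extract S, bounds and id orderings as dense numpy arrays."""
    S = create_stoichiometric_matrix(model, array_type="dense")
    return NetworkArrays(
        S=S,
        lower_bounds=np.array([r.lower_bound for r in model.reactions], dtype=float),
        upper_bounds=np.array([r.upper_bound for r in model.reactions], dtype=float),
        reaction_ids=[r.id for r in model.reactions],
        metabolite_ids=[m.id for m in model.metabolites],
    )


def steady_state_residual(model: cobra.Model, fluxes: pd.Series) -> float:
    """Max |S.v| row residual of a flux vector — the steady-state check."""
    arrays = network_arrays(model)
    v = fluxes.reindex(arrays.reaction_ids).to_numpy()
    return float(np.abs(arrays.S @ v).max())
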