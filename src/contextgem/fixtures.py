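"""Desk-scale test fixtures: toy metabolic models and synthetic expression.

Genome-scale inputs (a human template model, RNA-seq panels, CRISPR
screens) are far too large to ship or download in tests, so every stage of
the pipeline is exercised on small generated stand-ins with recorded
ground truth:

* :func:`make_toy_model` builds named toy network topologies (linear
  chains, diamonds, dead ends, isozyme GPR patterns, parallel paths,
  minimal-medium networks) as fully valid, SBML-serialisable cobra models,
  together with a machine-readable truth dictionary (blocked reactions,
  essential genes, expected minimal subnetworks).
* :func:`synth_expression` generates TPM-like transcript-by-sample
  matrices with planted active/inactive transcript sets and a realistic
  fraction of unexpressed transcripts.
* the ``brute_force_*`` oracles in :mod:`contextgem.oracles` (re-exported
  here) provide exhaustive-enumeration answers on these fixtures.

Biomass reactions in all toys are single-metabolite sinks; no attempt is
made to mimic realistic biomass composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .oracles import (  # noqa: F401  (re-exported fixture oracles)
    brute_force_blocked,
    brute_force_consistent,
    brute_force_min_consistent_superset,
    brute_force_min_gapfill,
    brute_force_tinit_objective,
)

__all__ = [
    "TOPOLOGIES",
    "make_toy_model",
    "random_toy_model",
    "synth_expression",
    "brute_force_blocked",
    "brute_force_consistent",
    "brute_force_min_consistent_superset",
    "brute_force_min_gapfill",
    "brute_force_tinit_objective",
]

TOPOLOGIES = ("chain", "diamond", "dead_end", "isozyme", "parallel_paths", "minimal_medium")

UB = 1000.0


def _met(mid: str, compartment: str = "c") -> cobra.Metabolite:
    return cobra.Metabolite(mid, compartment=compartment)


def _rxn(rid, mets, lb=0.0, ub=UB, gpr=""):
    r = cobra.Reaction(rid)
    r.add_metabolites(mets)
    r.bounds = (lb, ub)
    if gpr:
        r.gene_reaction_rule = gpr
    return r


def make_toy_model(
    topology: str,
    n: int = 3,
    uptake: float = 10.0,
    reversible_internal: bool = False,
) -> tuple[cobra.Model, dict]:
    """Build a named toy network; returns ``(model, ground_truth)``.

    ``ground_truth`` records, per topology, the facts the tests assert:
    blocked reactions, essential genes, the maximum biomass flux with
    ``uptake`` substrate available, minimal subnetworks, media behaviour.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; options: {TOPOLOGIES}")
    builder = {
        "chain": _build_chain,
        "diamond": _build_diamond,
        "dead_end": _build_dead_end,
        "isozyme": _build_isozyme,
        "parallel_paths": _build_parallel_paths,
        "minimal_medium": _build_minimal_medium,
    }[topology]
    return builder(n=n, uptake=uptake, reversible_internal=reversible_internal)


def _finish(model: cobra.Model, objective: str):
    model.objective = objective
    return model


def _build_chain(n=3, uptake=10.0, reversible_internal=False):
    """EX_A0 -> R1 -> ... -> Rn -> BIOMASS, one gene per internal step."""
    if n < 1:
        raise ValueError("chain needs n >= 1 internal reactions")
    model = cobra.Model("chain")
    mets = [_met("A0", "e")] + [_met(f"A{i}") for i in range(1, n + 1)]
    rxns = [_rxn("EX_A0", {mets[0]: -1}, lb=-uptake, ub=UB)]
    lb_int = -UB if reversible_internal else 0.0
    for i in range(1, n + 1):
        rxns.append(_rxn(f"R{i}", {mets[i - 1]: -1, mets[i]: 1}, lb=lb_int, gpr=f"g{i}"))
    rxns.append(_rxn("BIOMASS", {mets[n]: -1}))
    model.add_reactions(rxns)
    truth = {
        "max_growth": uptake,
        "essential_genes": {f"g{i}" for i in range(1, n + 1)},
        "blocked": set(),
        "n_reactions": n + 2,
        "n_metabolites": n + 1,
    }
    return _finish(model, "BIOMASS"), truth


def _build_diamond(n=3, uptake=10.0, reversible_internal=False):
    """Two routes A -> Z: a 2-reaction short path and a 3-reaction long path."""
    model = cobra.Model("diamond")
    A = _met("A", "e")
    P, Q1, Q2, Z = (_met(m) for m in ("P", "Q1", "Q2", "Z"))
    rxns = [
        _rxn("EX_A", {A: -1}, lb=-uptake, ub=UB),
        _rxn("S1", {A: -1, P: 1}, gpr="gs1"),
        _rxn("S2", {P: -1, Z: 1}, gpr="gs2"),
        _rxn("L1", {A: -1, Q1: 1}, gpr="gl1"),
        _rxn("L2", {Q1: -1, Q2: 1}, gpr="gl2"),
        _rxn("L3", {Q2: -1, Z: 1}, gpr="gl3"),
        _rxn("BIOMASS", {Z: -1}),
    ]
    model.add_reactions(rxns)
    truth = {
        "max_growth": uptake,
        "short_path": {"S1", "S2"},
        "long_path": {"L1", "L2", "L3"},
        "essential_genes": set(),  # each path backs the other up
        "blocked": set(),
    }
    return _finish(model, "BIOMASS"), truth


def _build_dead_end(n=3, uptake=10.0, reversible_internal=False):
    """A chain plus a reaction feeding a metabolite nothing consumes."""
    model, truth = _build_chain(n=n, uptake=uptake, reversible_internal=reversible_internal)
    D = _met("DEAD")
    model.add_reactions([_rxn("R_DEAD", {model.metabolites.get_by_id("A1"): -1, D: 1}, gpr="gdead")])
    truth = dict(truth)
    truth["blocked"] = {"R_DEAD"}
    truth["n_reactions"] += 1
    return model, truth


def _build_isozyme(n=3, uptake=10.0, reversible_internal=False):
    """3-step chain exercising sole-isoform, isozyme-backup and complex GPRs."""
    model, _ = _build_chain(n=3, uptake=uptake)
    model.reactions.R1.gene_reaction_rule = "g1"
    model.reactions.R2.gene_reaction_rule = "g2a or g2b"
    model.reactions.R3.gene_reaction_rule = "g3a and g3b"
    truth = {
        "max_growth": uptake,
        "essential_genes": {"g1", "g3a", "g3b"},
        "nonessential_genes": {"g2a", "g2b"},
        "blocked": set(),
    }
    return model, truth


def _build_parallel_paths(n=2, uptake=10.0, reversible_internal=False):
    """Two disjoint 2-reaction routes to biomass with separate gene sets."""
    model = cobra.Model("parallel_paths")
    A = _met("A", "e")
    B, C, Z = (_met(m) for m in ("B", "C", "Z"))
    rxns = [
        _rxn("EX_A", {A: -1}, lb=-uptake, ub=UB),
        _rxn("P1", {A: -1, B: 1}, gpr="gp1"),
        _rxn("P2", {B: -1, Z: 1}, gpr="gp2"),
        _rxn("N1", {A: -1, C: 1}, gpr="gn1"),
        _rxn("N2", {C: -1, Z: 1}, gpr="gn2"),
        _rxn("BIOMASS", {Z: -1}),
    ]
    model.add_reactions(rxns)
    truth = {
        "max_growth": uptake,
        "path_a": {"P1", "P2"},
        "path_b": {"N1", "N2"},
        "blocked": set(),
    }
    return _finish(model, "BIOMASS"), truth


def _build_minimal_medium(n=3, uptake=10.0, reversible_internal=False):
    """Growth requires substrate X; Y is usable (secreted as V) but not growth-supporting."""
    model = cobra.Model("minimal_medium")
    X, Y, V = (_met(m, "e") for m in ("X", "Y", "V"))
    Z = _met("Z")
    rxns = [
        _rxn("EX_X", {X: -1}, lb=-uptake, ub=UB),
        _rxn("EX_Y", {Y: -1}, lb=-uptake, ub=UB),
        _rxn("EX_V", {V: -1}, lb=0.0, ub=UB),
        _rxn("R_XZ", {X: -1, Z: 1}, gpr="gx"),
        _rxn("R_YV", {Y: -1, V: 1}, gpr="gy"),
        _rxn("BIOMASS", {Z: -1}),
    ]
    model.add_reactions(rxns)
    truth = {
        "max_growth": uptake,
        "growth_medium": {"X"},
        "non_growth_medium": {"Y"},
        "blocked": set(),
    }
    return _finish(model, "BIOMASS"), truth


def random_toy_model(seed: int, uptake_range=(1.0, 20.0)) -> tuple[cobra.Model, dict]:
    """A seed-deterministic random small model for property sweeps.

    Picks a growth-capable topology, a random uptake bound and random
    reversibility of internal reactions.
    """
    rng = np.random.default_rng(seed)
    topology = ("chain", "diamond", "parallel_paths")[rng.integers(0, 3)]
    uptake = float(np.round(rng.uniform(*uptake_range), 3))
    n = int(rng.integers(2, 5))
    reversible = bool(rng.integers(0, 2))
    model, truth = make_toy_model(
        topology, n=n, uptake=uptake, reversible_internal=(reversible and topology == "chain")
    )
    truth["topology"] = topology
    truth["seed"] = seed
    return model, truth


# ---------------------------------------------------------------------------
# Synthetic expression
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpressionSpec:
    """Stated world of the expression generator.

    TPM values are log-normal (``exp(N(mu, sigma))``) with a fraction of
    transcripts unexpressed (all-zero rows, as for silent genes in a TPM
    matrix).  Planted active and inactive sets sit ``separation``-fold
    above and below the background mean, so they are recoverable by the
    localT2 strategy at its default percentiles.
    """

    n_transcripts: int = 1000
    n_samples: int = 20
    seed: int = 0
    zero_fraction: float = 0.3
    active_fraction: float = 0.1
    inactive_fraction: float = 0.1
    separation: float = 8.0
    log_mean: float = np.log(10.0)
    log_sigma: float = 0.5

    def __post_init__(self):
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.zero_fraction + self.active_fraction + self.inactive_fraction > 1:
            raise ValueError("planted and zero fractions exceed the transcript count")


def synth_expression(spec: SyntheticExpressionSpec | None = None, **kwargs):
    """Generate a TPM-like matrix; returns ``(expression, truth)``.

    ``truth`` lists the planted-active, planted-inactive and unexpressed
    transcript ids.  Generation is a pure function of the spec (same seed,
    same matrix).
    """
    spec = spec or SyntheticExpressionSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_transcripts, spec.n_samples
    ids = [f"t{i:05d}" for i in range(n)]

    n_zero = round(spec.zero_fraction * n)
    n_act = round(spec.active_fraction * n)
    n_inact = round(spec.inactive_fraction * n)
    perm = rng.permutation(n)
    zero_idx = perm[:n_zero]
    act_idx = perm[n_zero : n_zero + n_act]
    inact_idx = perm[n_zero + n_act : n_zero + n_act + n_inact]

    mu = np.full(n, spec.log_mean)
    mu[act_idx] += np.log(spec.separation)
    mu[inact_idx] -= np.log(spec.separation)
    values = np.exp(rng.normal(mu[:, None], spec.log_sigma, size=(n, s)))
    values[zero_idx, :] = 0.0
    expr = pd.DataFrame(values, index=ids, columns=[f"s{j:03d}" for j in range(s)])
    truth = {
        "planted_active": {ids[i] for i in act_idx},
        "planted_inactive": {ids[i] for i in inact_idx},
        "unexpressed": {ids[i] for i in zero_idx},
        "spec": spec,
    }
    return expr, truth
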