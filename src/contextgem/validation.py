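"""Model validation: gene essentiality, multiclass MCC, flux activity calls,
and parameter-importance regression.

A context-specific model is scored against two kinds of experimental data:

* **Gene essentiality screens** (CRISPR, CERES scores).  Each gene is
  knocked out in silico by disabling the reactions its deletion disables
  (GPR propagation), biomass is re-optimised with FBA, and the knockout is
  called lethal when the mutant optimum falls below a fraction (default
  0.1%) of the wild-type optimum or the problem becomes infeasible.
  Experimental lethality comes from thresholding CERES scores (more
  negative = more essential).
* **Measured fluxes.**  Predicted and measured fluxes are discretised into
  forward-active / reverse-active / null and compared with the multiclass
  Matthews correlation coefficient (MCC).

Parameter importance across a reconstruction grid is quantified by an
ordinary-least-squares fit of MCC on one-hot encoded parameter options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core as mc
from .gpr import knockout_affected_reactions

__all__ = [
    "CERES_THRESHOLDS",
    "EssentialityReport",
    "essentiality_screen",
    "discretize_ceres",
    "essentiality_mcc",
    "confusion_counts",
    "mcc",
    "discretize_flux",
    "compare_flux_activity",
    "parameter_importance",
]

#: Five CERES thresholds evenly spaced across [-1.5, -0.5].
CERES_THRESHOLDS = (-1.5, -1.25, -1.0, -0.75, -0.5)

DEFAULT_LETHALITY_FRACTION = 0.001  # mutant biomass below 0.1% of wild type = lethal
FLUX_CLASSES = ("forward_active", "reverse_active", "null")


@dataclass
class EssentialityReport:
    """Per-gene knockout outcome of an in-silico essentiality screen."""

    table: pd.DataFrame  # index gene; columns: ratio, predicted_essential, in_model
    wild_type_growth: float
    lethality_fraction: float

    @property
    def predicted_essential(self) -> set[str]:
        return set(self.table.index[self.table["predicted_essential"]])


def essentiality_screen(
    context_model,
    genes: list[str],
    lethality_fraction: float = DEFAULT_LETHALITY_FRACTION,
    objective: str | None = None,
) -> EssentialityReport:
    """Simulate single-gene knockouts and classify each as lethal or viable.

    Genes absent from the model disable nothing and are predicted
    non-essential (screens contain many non-metabolic genes).  Reaction
    bounds are restored exactly between knockouts.  A non-growing wild type
    is an error: the lethality ratio would be undefined.
    """
    wt = mc.fba(context_model, objective=objective)
    if not wt.feasible or wt.objective_value <= 0:
        raise ValueError("wild-type model does not grow; essentiality is undefined")

    model_genes = {g.id for g in context_model.genes}
    records = []
    saved_bounds = {r.id: r.bounds for r in context_model.reactions}
    for gene in genes:
        if gene not in model_genes:
            records.append((gene, 1.0, False, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            affected = knockout_affected_reactions(gene, context_model)
        # only reactions still open can be knocked out meaningfully
        for rid in affected:
            context_model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        sol = mc.fba(context_model, objective=objective)
        for rid in affected:
            context_model.reactions.get_by_id(rid).bounds = saved_bounds[rid]
        if not sol.feasible:
            ratio = 0.0  # infeasible knockouts are non-viable
        else:
            ratio = sol.objective_value / wt.objective_value
        records.append((gene, ratio, ratio < lethality_fraction, True))
    table = pd.DataFrame(
        records, columns=["gene", "ratio", "predicted_essential", "in_model"]
    ).set_index("gene")
    return EssentialityReport(table, wt.objective_value, lethality_fraction)


def discretize_ceres(scores: pd.Series, threshold: float) -> pd.Series:
    """Experimental lethality call: essential iff CERES score <= threshold.

    Genes with missing scores are excluded (logged via warning).
    """
    missing = scores.index[scores.isna()]
    if len(missing):
        warnings.warn(f"excluding {len(missing)} genes with missing CERES scores")
    kept = scores.dropna()
    return kept <= threshold


def essentiality_mcc(
    report: EssentialityReport,
    experimental: pd.Series,
    model_genes_only: bool = False,
) -> float:
    """MCC between predicted and experimental lethality calls.

    ``experimental`` is a boolean series (essential = True) as produced by
    :func:`discretize_ceres`.  By default all screened genes in common are
    scored, with off-model genes predicted non-essential; with
    ``model_genes_only`` scoring is restricted to genes carried by the model.
    """
    table = report.table
    if model_genes_only:
        table = table[table["in_model"]]
    common = table.index.intersection(experimental.index)
    if len(common) == 0:
        raise ValueError("no genes shared between screen and predictions")
    pred = table.loc[common, "predicted_essential"].astype(bool)
    return mcc(list(pred), list(experimental.loc[common].astype(bool)))


# ---------------------------------------------------------------------------
# Multiclass MCC
# ---------------------------------------------------------------------------

def confusion_counts(predicted, actual):
    """Per-class prediction counts ``p_k``, truth counts ``t_k``, correct ``c``, size ``s``."""
    predicted = list(predicted)
    actual = list(actual)
    if len(predicted) != len(actual):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(actual)} labels")
    classes = sorted(set(predicted) | set(actual), key=str)
    p = np.array([sum(x == k for x in predicted) for k in classes], dtype=float)
    t = np.array([sum(x == k for x in actual) for k in classes], dtype=float)
    c = float(sum(a == b for a, b in zip(predicted, actual)))
    return p, t, c, float(len(actual))


def mcc(predicted, actual) -> float:
    """Multiclass Matthews correlation coefficient.

    ``MCC = (c*s - p.t) / sqrt((s^2 - p.p) * (s^2 - t.t))`` with per-class
    prediction counts ``p``, truth counts ``t``, total correct ``c`` and
    sample count ``s``.  Degenerate denominators (constant predictor or
    constant labels) yield 0.  Reduces to the familiar binary formula for
    two classes.
    """
    p, t, c, s = confusion_counts(predicted, actual)
    num = c * s - float(p @ t)
    den = (s**2 - float(p @ p)) * (s**2 - float(t @ t))
    if den <= 0:
        return 0.0
    return num / np.sqrt(den)


# ---------------------------------------------------------------------------
# Flux activity
# ---------------------------------------------------------------------------

def discretize_flux(fluxes: pd.Series, tol: float = 1e-6) -> pd.Series:
    """Three-way call per reaction: forward-active, reverse-active or null.

    The tolerance band is symmetric around zero: ``|v| <= tol`` is null.
    """
    def call(v: float) -> str:
        if v > tol:
            return "forward_active"
        if v < -tol:
            return "reverse_active"
        return "null"

    return fluxes.map(call)


def compare_flux_activity(
    predicted: pd.Series,
    measured: pd.Series,
    sign_map: pd.Series | None = None,
) -> float:
    """Multiclass MCC between predicted and measured flux-activity calls.

    Both inputs are class series indexed by reaction id; scoring happens on
    the id intersection (empty intersection is an error).  ``sign_map``
    (+1/-1 per reaction) reconciles direction conventions between the
    measurement and the model: -1 swaps forward and reverse in the measured
    call.
    """
    common = predicted.index.intersection(measured.index)
    if len(common) == 0:
        raise ValueError("no overlapping reactions between prediction and measurement")
    meas = measured.loc[common].copy()
    if sign_map is not None:
        flip = sign_map.reindex(common).fillna(1)
        swap = {"forward_active": "reverse_active", "reverse_active": "forward_active", "null": "null"}
        meas = pd.Series(
            [swap[v] if flip[i] < 0 else v for i, v in meas.items()], index=common
        )
    return mcc(list(predicted.loc[common]), list(meas))


# ---------------------------------------------------------------------------
# Parameter importance
# ---------------------------------------------------------------------------

def parameter_importance(configs, scores) -> pd.DataFrame:
    """OLS coefficients of one-hot encoded reconstruction parameters on MCC.

    Each parameter is expanded into indicator columns; the alphabetically
    first level of each parameter is dropped as the reference, so every
    coefficient reads as the MCC shift of choosing that option over the
    reference.  A "not applicable" level (a percentile unused by the
    strategy) is also treated as reference: it is fully determined by the
    strategy columns and would otherwise make the design singular.
    Parameters taking a single value across the grid are excluded.  Returns
    a DataFrame indexed ``parameter=value`` with ``coef`` and ``stderr``
    columns (the intercept appears as ``intercept=``).

    Raises on a rank-deficient design (perfectly collinear options).
    """
    import statsmodels.api as sm

    records = []
    for cfg in configs:
        d = cfg if isinstance(cfg, dict) else {
            "algorithm": cfg.algorithm, "strategy": cfg.strategy,
            "p_gmax": cfg.p_gmax, "p_gmin": cfg.p_gmin,
            "p_local": cfg.p_local, "or_fn": cfg.or_fn, "and_fn": cfg.and_fn,
        }
        records.append({k: "none" if v is None else str(v) for k, v in d.items()})
    frame = pd.DataFrame(records)
    y = np.asarray(scores, dtype=float)
    if len(frame) != len(y):
        raise ValueError("configs and scores must have equal length")

    varying = [c for c in frame.columns if frame[c].nunique() > 1]
    if not varying:
        raise ValueError("no parameter varies across the supplied configurations")
    pieces = []
    for col in varying:
        levels = sorted(frame[col].unique())
        reference = {"none"} if "none" in levels else set()
        remaining = [lv for lv in levels if lv not in reference]
        reference.add(remaining[0])  # alphabetically first real level
        for lv in levels:
            if lv not in reference:
                pieces.append((frame[col] == lv).astype(float).rename(f"{col}={lv}"))
    X = pd.concat(pieces, axis=1)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            "one-hot design is rank-deficient after dropping reference levels; "
            f"collinear columns among: {list(X.columns)}"
        )
    fit = sm.OLS(y, X).fit()
    out = pd.DataFrame({"coef": fit.params, "stderr": fit.bse})
    return out.rename(index={"const": "intercept="})
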