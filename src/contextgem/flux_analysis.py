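"""Downstream analysis of predicted flux distributions.

pFBA flux matrices (models/samples by reactions) feed decomposition and
classification tasks.  The steps here are the bespoke pieces of that
workflow; PCA and classifiers themselves are delegated to scikit-learn.

* :func:`scale_fluxes` — sigmoid transform ``s(x) = a/(1 + e^x) + 1``
  applied elementwise before any statistics; with the default ``a = -2``
  this is exactly ``tanh(x/2)``: odd, sign-preserving and bounded in
  (-1, 1), so huge fluxes are tamed without losing directionality.
* :func:`select_flux_features` — drop near-constant fluxes, then keep the
  ``n_top`` fluxes most associated with a discrete label by one-way ANOVA.
* :func:`pathway_loading_summary` — compress PCA loadings to pathway level:
  per component, the mean over a pathway's reactions of ``|w| / max|w|``.
* :func:`grouped_kfold` — cross-validation folds that split by cell line,
  so no cell line contributes flux distributions to both train and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScalingConfig",
    "scale_fluxes",
    "select_flux_features",
    "pathway_loading_summary",
    "grouped_kfold",
]


@dataclass
class ScalingConfig:
    """Settings for flux scaling and feature selection.

    ``a`` is the sigmoid range parameter; -2 is the only value for which the
    transform is odd and sign-preserving.  ``variance_floor`` applies to
    scaled fluxes.  ``n_top_features`` defaults to 200 significant fluxes.
    """

    a: float = -2.0
    variance_floor: float = 1e-8
    n_top_features: int = 200

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("a must be nonzero (a = 0 gives a constant map)")


def scale_fluxes(values, cfg: ScalingConfig | None = None):
    """Elementwise sigmoid scaling ``s(x) = a * 1/(1 + e^x) + 1``."""
    cfg = cfg or ScalingConfig()
    arr = np.asarray(values, dtype=float)
    out = cfg.a / (1.0 + np.exp(arr)) + 1.0
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def select_flux_features(
    X: pd.DataFrame,
    labels,
    n_top: int = 200,
    variance_floor: float = 1e-8,
) -> pd.DataFrame:
    """Variance filter followed by one-way ANOVA ranking across label groups.

    Columns with variance below the floor are dropped; the remaining
    columns are ranked by ANOVA p-value (smaller is better) of their values
    grouped by ``labels``, with ties broken by larger F statistic and then
    original column order, and the best ``n_top`` kept in original column
    order.  If fewer columns survive the variance filter than requested,
    all survivors are returned with a warning.
    """
    labels = pd.Series(list(labels), index=X.index)
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("ANOVA needs >= 2 classes with >= 2 rows each")

    variances = X.var(axis=0, ddof=1)
    survivors = X.loc[:, variances >= variance_floor]
    if survivors.shape[1] <= n_top:
        if survivors.shape[1] < n_top:
            warnings.warn(
                f"only {survivors.shape[1]} columns survive the variance filter "
                f"(requested {n_top})"
            )
        return survivors

    groups = [survivors[labels == g] for g in counts.index]
    fstat, pval = stats.f_oneway(*[g.to_numpy() for g in groups], axis=0)
    order = pd.DataFrame(
        {"p": pval, "negF": -fstat, "pos": np.arange(survivors.shape[1])},
        index=survivors.columns,
    ).sort_values(["p", "negF", "pos"])
    chosen = order.index[:n_top]
    keep = [c for c in survivors.columns if c in set(chosen)]
    return survivors[keep]


def pathway_loading_summary(
    loadings: pd.DataFrame,
    pathway_map: pd.Series,
) -> pd.DataFrame:
    """Summarise PCA loadings (reactions x components) at pathway level.

    For component ``c`` and pathway ``P`` the score is the mean over
    reactions ``r`` in ``P`` of ``|w_rc| / max_r' |w_r'c|`` — the
    normalisation is per component, which makes the score invariant to
    rescaling any component's loading vector.  Reactions without a pathway
    assignment fall into an ``"unassigned"`` bucket.  Scores lie in [0, 1].
    An all-zero loading vector is an error (the ratio is undefined).
    """
    maxabs = loadings.abs().max(axis=0)
    if (maxabs == 0).any():
        bad = list(maxabs.index[maxabs == 0])
        raise ValueError(f"all-zero loading vector for component(s) {bad}")
    ratios = loadings.abs() / maxabs
    pathways = pathway_map.reindex(loadings.index).fillna("unassigned")
    return ratios.groupby(pathways).mean()


def grouped_kfold(groups, k: int, seed: int | None = None):
    """K folds that partition *groups* (cell lines), not rows.

    Returns a list of ``(train_rows, test_rows)`` index-array pairs.  Every
    row appears in exactly one test fold and no group is split across train
    and test within a fold.  Groups are shuffled (seeded) before being
    dealt round-robin into folds; with ``seed=None`` the assignment is the
    sorted deterministic one.
    """
    groups = pd.Series(list(groups))
    unique = sorted(groups.unique(), key=str)
    if k > len(unique):
        raise ValueError(f"k={k} exceeds the number of distinct groups ({len(unique)})")
    if k < 2:
        raise ValueError("k must be >= 2")
    unique = np.array(unique, dtype=object)
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(unique)
    fold_of = {g: i % k for i, g in enumerate(unique)}
    assignment = groups.map(fold_of).to_numpy()
    rows = np.arange(len(groups))
    return [(rows[assignment != f], rows[assignment == f]) for f in range(k)]
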