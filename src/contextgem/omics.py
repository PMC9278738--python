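"""Transcript activity scoring (TAS) from TPM expression matrices.

RNA-seq abundances (TPM) are turned into signed transcript activity scores
by comparing each transcript's expression ``x`` against reference
thresholds derived from the dataset itself:

* per-transcript **local** thresholds ``l(y)`` — a quantile of the
  transcript's expression across samples;
* **global** thresholds ``g_min``/``g_max`` — the mean of a local
  threshold set, condensing the whole dataset into one value.

Three strategies are supported.  ``global`` scores every transcript as
``log2(x / g_max)``.  ``localT1`` uses the local threshold below ``g_max``
and the global threshold above it.  ``localT2`` adds a confident-inactive
state below ``g_min``: scores are ``1 + log2(x / g_max)`` for confidently
active transcripts (so the active range starts at 1), ``log2(x / g_min)``
(≤ 0) for confidently inactive ones, and ``log2(x / l(y))`` clipped to
[-1, 1] in the uncertain band between the two global thresholds, where the
sign alone encodes the local activity call.

Scores are log-ratios; the base (default 2, the expression fold-change
convention) is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STRATEGIES",
    "ThresholdSet",
    "local_thresholds",
    "global_threshold",
    "thresholds_for_strategy",
    "compute_tas",
    "compute_tas_matrix",
]

STRATEGIES = ("global", "localT1", "localT2")

#: Finite stand-in for log(0) on branches whose range is unbounded below.
SCORE_FLOOR = -10.0


@dataclass
class ThresholdSet:
    """Reference thresholds for one TAS strategy.

    Attributes
    ----------
    g_max : float
        Upper global threshold; expression at or above it is confidently
        active.  Required by every strategy.
    g_min : float or None
        Lower global threshold (localT2 only); expression at or below it
        is confidently inactive.  Must satisfy ``g_min <= g_max``.
    local : pandas.Series or None
        Per-transcript local thresholds ``l(y)`` (localT1/localT2).
    percentiles : dict
        Bookkeeping of the percentile settings that produced the thresholds.
    """

    g_max: float
    g_min: float | None = None
    local: pd.Series | None = None
    percentiles: dict | None = None

    def __post_init__(self):
        if self.g_min is not None and self.g_min > self.g_max:
            raise ValueError(f"g_min ({self.g_min}) must be <= g_max ({self.g_max})")
        if self.local is not None and (self.local < 0).any():
            raise ValueError("local thresholds must be non-negative")

    def validate_for(self, strategy: str) -> None:
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
        if strategy in ("localT1", "localT2") and self.local is None:
            raise ValueError(f"strategy {strategy!r} requires per-transcript local thresholds")
        if strategy == "localT2" and self.g_min is None:
            raise ValueError("strategy 'localT2' requires g_min")


def local_thresholds(expression: pd.DataFrame, percentile: float) -> pd.Series:
    """Per-transcript threshold: the given percentile of expression across samples.

    Uses the linear-interpolation quantile definition (numpy default), so
    thresholds are reproducible bit-for-bit.  Requires at least two samples;
    a single-sample quantile across samples is undefined for local
    thresholding purposes.
    """
    if expression.shape[1] < 2:
        raise ValueError("local thresholding requires at least 2 samples")
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative (TPM)")
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    q = np.quantile(expression.to_numpy(), percentile / 100.0, axis=1, method="linear")
    return pd.Series(q, index=expression.index, name=f"local_p{percentile:g}")


def global_threshold(local: pd.Series) -> float:
    """Condense a local threshold set into one global value: its arithmetic mean."""
    if len(local) == 0:
        raise ValueError("empty threshold vector")
    return float(local.mean())


def thresholds_for_strategy(
    expression: pd.DataFrame,
    strategy: str,
    p_gmax: float,
    p_gmin: float | None = None,
    p_local: float | None = None,
) -> ThresholdSet:
    """Build the :class:`ThresholdSet` a strategy needs from quantile settings.

    Global thresholds are means of the local threshold set at the requested
    percentile; the local set at ``p_local`` is carried along for the
    local strategies.
    """
    g_max = global_threshold(local_thresholds(expression, p_gmax))
    g_min = None
    local = None
    if strategy == "localT2":
        if p_gmin is None:
            raise ValueError("localT2 requires p_gmin")
        g_min = global_threshold(local_thresholds(expression, p_gmin))
    if strategy in ("localT1", "localT2"):
        if p_local is None:
            raise ValueError(f"{strategy} requires p_local")
        local = local_thresholds(expression, p_local)
    ts = ThresholdSet(
        g_max=g_max,
        g_min=g_min,
        local=local,
        percentiles={"p_gmax": p_gmax, "p_gmin": p_gmin, "p_local": p_local},
    )
    ts.validate_for(strategy)
    return ts


def _log_ratio(x: np.ndarray, threshold: np.ndarray | float, base: float) -> np.ndarray:
    """log_base(x / t) with log(0) mapped to -inf (handled by the caller)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(x / threshold) / np.log(base)


def compute_tas(
    expression: pd.Series,
    strategy: str,
    thresholds: ThresholdSet,
    log_base: float = 2.0,
    floor: float = SCORE_FLOOR,
) -> pd.Series:
    """Score one sample's transcripts under a thresholding strategy.

    Branch boundaries are assigned to the confident outer states: ``x >=
    g_max`` always takes the active branch and, under localT2, ``x <=
    g_min`` the inactive branch.  Zero expression yields the configured
    ``floor`` on branches whose range is unbounded below; on the clipped
    localT2 intermediate branch the clip itself bounds the score at -1.
    """
    thresholds.validate_for(strategy)
    x = expression.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative (TPM)")
    g_max = thresholds.g_max

    if strategy == "global":
        tas = _log_ratio(x, g_max, log_base)
    elif strategy == "localT1":
        local = thresholds.local.reindex(expression.index).to_numpy(dtype=float)
        high = x >= g_max
        tas = np.where(high, _log_ratio(x, g_max, log_base), _log_ratio(x, local, log_base))
    else:  # localT2
        g_min = thresholds.g_min
        local = thresholds.local.reindex(expression.index).to_numpy(dtype=float)
        high = x >= g_max
        low = x <= g_min
        mid_raw = np.clip(_log_ratio(x, local, log_base), -1.0, 1.0)
        tas = np.where(
            high,
            1.0 + _log_ratio(x, g_max, log_base),
            np.where(low, _log_ratio(x, g_min, log_base), mid_raw),
        )

    tas = np.where(np.isneginf(tas), floor, tas)
    return pd.Series(tas, index=expression.index, name=expression.name)


def compute_tas_matrix(
    expression: pd.DataFrame,
    strategy: str,
    thresholds: ThresholdSet,
    log_base: float = 2.0,
    floor: float = SCORE_FLOOR,
) -> pd.DataFrame:
    """Score every sample (column) of an expression matrix; see :func:`compute_tas`."""
    cols = {
        sample: compute_tas(expression[sample], strategy, thresholds, log_base, floor)
        for sample in expression.columns
    }
    return pd.DataFrame(cols)


def read_expression(path: str, sep: str = "\t") -> pd.DataFrame:
    """Read a transcript-by-sample TPM matrix from delimited text."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids: {dups[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative entries")
    return df


def write_tas(tas: pd.DataFrame, path: str, strategy: str, thresholds: ThresholdSet) -> None:
    """Write a TAS matrix as TSV plus a JSON sidecar with strategy metadata."""
    import json
    from pathlib import Path

    tas.to_csv(path, sep="\t")
    meta = {
        "strategy": strategy,
        "g_max": thresholds.g_max,
        "g_min": thresholds.g_min,
        "percentiles": thresholds.percentiles,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
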