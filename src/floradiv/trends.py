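"""Sampling-bias diagnostics: effort series, rank correlations, σ-scaling.

A strong positive rank correlation between the number of data entries per
stage and sampled-in-bin richness is the classic symptom of a
sampling-driven diversity curve.  Correlations use Spearman's r_s; a
correlation is flagged *strong* when |r_s| > 0.6 and *significant* when the
two-sided p < 0.05.  For the short series typical of stage-binned data
(n = 6 bins) the p-value is computed by exact enumeration of all n!
permutations whenever there are no ties and n ≤ 9; otherwise the usual
t-approximation on average ranks is used.

For visual trend comparison, series are mean-centred and scaled to unit
sample standard deviation (n−1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedResultError
from .records import OccurrenceRecordSet

__all__ = ["CorrelationResult", "ScaledSeries", "center_scale", "entries_per_stage", "spearman"]

STRONG_THRESHOLD = 0.6
ALPHA = 0.05


def entries_per_stage(records: OccurrenceRecordSet) -> pd.Series:
    """Number of occurrence entries per bin (sentinel stages excluded)."""
    df = records.in_interval
    counts = df["stage"].value_counts()
    return pd.Series(
        [int(counts.get(name, 0)) for name in records.stage_scale.names],
        index=pd.Index(records.stage_scale.names, name="stage"),
        name="n_entries",
    )


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    p: float
    n: int
    method: str  # "exact-permutation" or "t-approximation"

    @property
    def strong(self) -> bool:
        return abs(self.r_s) > STRONG_THRESHOLD

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided p by exhaustive permutation of one rank vector."""
    n = len(rx)
    denom = n * (n * n - 1)
    hits = 0
    total = 0
    for perm in permutations(ry):
        d = rx - np.asarray(perm)
        r = 1.0 - 6.0 * float(d @ d) / denom
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def spearman(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with a two-sided significance probability."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("Spearman correlation undefined for a constant series")

    r_s = float(stats.spearmanr(x, y).statistic)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if not ties and n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_p(rx, ry, r_s)
        method = "exact-permutation"
    else:
        if abs(r_s) >= 1.0:
            p = 0.0
        else:
            t = r_s * np.sqrt((n - 2) / (1.0 - r_s * r_s))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        method = "t-approximation"
    return CorrelationResult(r_s=r_s, p=p, n=n, method=method)


@dataclass(frozen=True)
class ScaledSeries:
    values: np.ndarray
    source_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def center_scale(series, label: str = "") -> ScaledSeries:
    """Mean-centre a series and scale it to its sample standard deviation."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise UndefinedResultError("cannot scale a constant series")
    return ScaledSeries(values=(x - x.mean()) / sd, source_label=label)
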