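"""Rank-based group comparisons and a normality gate.

Two-sided alternatives throughout, alpha = 0.05 by convention of the report
layer.  The rank-sum test uses the exact null for small tie-free samples and
the tie-corrected normal approximation (no continuity correction) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import DataError

__all__ = ["TestResult", "mann_whitney_u", "kruskal_wallis", "ks_normality"]

_EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # mann_whitney_u | kruskal_wallis | ks_normality
    n_per_group: tuple[int, ...]
    tie_correction_applied: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DataError(f"p-value {self.p_value} outside [0, 1]")


def _has_ties(*groups: Sequence[float]) -> bool:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided rank-sum test.

    Exact enumeration null when both groups have at most 10 values and there
    are no ties; tie-corrected normal approximation without continuity
    correction otherwise.
    """
    x, y = list(x), list(y)
    if len(x) < 2 or len(y) < 2:
        raise DataError("each group needs at least 2 values")
    ties = _has_ties(x, y)
    exact = not ties and max(len(x), len(y)) <= _EXACT_MAX_N
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann_whitney_u",
        n_per_group=(len(x), len(y)),
        tie_correction_applied=ties and not exact,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected H statistic against chi-square with k-1 df."""
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise DataError("each group needs at least 2 values")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        # no rank variation at all: H = 0 by definition
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            method="kruskal_wallis",
            n_per_group=tuple(len(g) for g in groups),
            tie_correction_applied=True,
        )
    h, p = stats.kruskal(*groups)
    return TestResult(
        statistic=float(h),
        p_value=float(p),
        method="kruskal_wallis",
        n_per_group=tuple(len(g) for g in groups),
        tie_correction_applied=_has_ties(*groups),
    )


def ks_normality(x: Sequence[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov distance against N(mean, sd) with the
    parameters estimated from the sample.

    The p-value comes from the asymptotic KS distribution and is
    anti-conservative when parameters are estimated (no Lilliefors
    correction); it is used here as a gate, not as a calibrated test.
    """
    arr = np.asarray(list(x), dtype=float)
    if arr.size < 4:
        raise DataError("normality gate needs at least 4 values")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise DataError("constant sample: normality test undefined")
    res = stats.kstest(arr, "norm", args=(float(arr.mean()), sd))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="ks_normality",
        n_per_group=(arr.size,),
    )
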