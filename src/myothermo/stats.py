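"""Descriptive cohort statistics and two-group comparisons.

Box-plot style five-number summaries (type-7 linear-interpolation
quartiles, 1.5*IQR outlier rule) and one-way ANOVA; with two groups the
ANOVA F statistic equals the square of the pooled-variance t statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "AnovaResult", "summarize", "one_way_anova"]


@dataclass(frozen=True)
class GroupSummary:
    variable: str
    group: str
    n: int
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float
    outliers: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class AnovaResult:
    variable: str
    F: float
    p: float
    significant: bool


def summarize(values: Sequence[float], variable: str = "", group: str = "") -> GroupSummary:
    """Moments plus five-number summary with 1.5*IQR outlier flagging."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = tuple(float(v) for v in x[(x < lo) | (x > hi)])
    return GroupSummary(
        variable=variable, group=group, n=int(x.size),
        mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        min=float(np.min(x)), q1=float(q1), median=float(med), q3=float(q3),
        max=float(np.max(x)), outliers=out,
    )


def one_way_anova(group_a: Sequence[float], group_b: Sequence[float],
                  variable: str = "", alpha: float = 0.05) -> AnovaResult:
    """Two-group one-way ANOVA (between/within decomposition).

    Delegates to scipy's F test; identical groups give F = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    F, p = sps.f_oneway(a, b)
    if np.isnan(F):  # zero within-group variance and equal means
        F, p = 0.0, 1.0
    return AnovaResult(variable=variable, F=float(F), p=float(p),
                       significant=bool(p < alpha))
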