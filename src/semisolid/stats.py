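"""Summary statistics shared by the report stages.

Means are arithmetic, SDs use the n-1 denominator, the two-sample test is
Welch's unequal-variance t (a pooled-variance option exists for fidelity to
classic Student), and correlations are Pearson product-moment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float  # NaN when n == 1
    n: int
    label: str = ""
    t: float | None = None
    p: float | None = None
    pearson_r: float | None = None


def mean_sd(values: Sequence[float], label: str = "") -> SummaryStat:
    """Arithmetic mean and sample SD (n-1); SD is NaN for a single value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("empty input")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return SummaryStat(mean=float(arr.mean()), sd=sd, n=int(arr.size), label=label)


def welch_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pooled: bool = False,
    label: str = "",
) -> SummaryStat:
    """Two-sided two-sample t-test (Welch by default, pooled optional).

    Degenerate variance handling: when both groups have zero variance the
    test statistic is taken in the limit — identical means give t = 0,
    p = 1; different means give t = +/-inf, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=pooled)
        t, p = float(t), float(p)
    diff = float(a.mean() - b.mean())
    sd = float(
        math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    )  # SE of the mean difference
    return SummaryStat(mean=diff, sd=sd, n=int(a.size + b.size), label=label, t=t, p=p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and equal length")
    if xa.size < 3:
        raise InsufficientDataError("need n >= 3 for a correlation")
    if xa.std() == 0 or ya.std() == 0:
        raise InvalidInputError("zero variance: correlation undefined")
    return float(sps.pearsonr(xa, ya).statistic)
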