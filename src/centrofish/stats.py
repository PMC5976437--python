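"""Condition comparisons: two-sided unpaired t-tests with effect sizes.

Welch's unequal-variance t-test is the default; ``classic=True`` restores
the pooled-variance Student's t-test.  Reported alongside the test are
the group means, the fold change ``mean_a / mean_b``, the percent change,
and a 95% confidence interval of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class ConditionComparison:
    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_difference: float          # mean_a - mean_b
    fold_change: float              # mean_a / mean_b
    percent_change: float           # 100 * (mean_a / mean_b - 1)
    t: float
    p: float
    ci_low: float                   # 95% CI of the mean difference
    ci_high: float
    degenerate: bool = False        # zero variance in both groups


def compare_conditions(values_a, values_b, label_a: str = "A",
                       label_b: str = "B",
                       classic: bool = False) -> ConditionComparison:
    """Two-sided unpaired t-test between two per-cell value vectors.

    Swapping the inputs negates the mean difference and ``t`` and inverts
    the fold change.  When both groups have zero variance and equal means
    the statistic is undefined; the comparison is flagged ``degenerate``
    with ``t = 0`` and ``p = 1``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs at least 2 cells")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    diff = mean_a - mean_b
    degenerate = a.std() == 0 and b.std() == 0

    if degenerate:
        t_stat, p_val = 0.0, 1.0
        ci_low = ci_high = diff
    else:
        res = sps.ttest_ind(a, b, equal_var=classic)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        ci = res.confidence_interval(0.95)
        ci_low, ci_high = float(ci.low), float(ci.high)

    fold = mean_a / mean_b if mean_b != 0 else np.inf
    return ConditionComparison(
        label_a=label_a, label_b=label_b,
        values_a=a, values_b=b,
        n_a=a.size, n_b=b.size,
        mean_a=mean_a, mean_b=mean_b,
        mean_difference=diff,
        fold_change=fold,
        percent_change=100.0 * (fold - 1.0) if np.isfinite(fold) else np.inf,
        t=t_stat, p=p_val,
        ci_low=ci_low, ci_high=ci_high,
        degenerate=degenerate,
    )


def t_confidence_interval(values, confidence: float = 0.95):
    """Student-t CI of the mean of one sample (n-1 degrees of freedom)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    mean = float(v.mean())
    if n < 2:
        return mean, np.nan, np.nan
    sem = v.std(ddof=1) / np.sqrt(n)
    half = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sem)
    return mean, mean - half, mean + half
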