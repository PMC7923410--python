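"""Estimator-agreement statistics and group comparisons.

``compare_estimator`` summarises how an SDNN estimate tracks the gold
standard across subjects: bias (mean +/- SD of estimate - truth, sample SD
convention), RMSE, Pearson r and a two-sided paired t-test on the
differences. ``group_ttest`` is the unpaired two-sample t-test (pooled
variance by default, Welch as an option) whose t-score measures how strongly
a feature separates the low- and high-risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

from .io_formats import ValidationError

__all__ = ["ComparisonReport", "compare_estimator", "group_ttest"]


@dataclass(frozen=True)
class ComparisonReport:
    """Agreement between an estimator and the gold standard over subjects."""

    n: int
    bias_mean_ms: float
    bias_sd_ms: float
    rmse_ms: float
    pearson_r: float
    t_statistic: float
    p_value: float
    test_kind: str = "paired"


def compare_estimator(truth, estimate) -> ComparisonReport:
    """Per-subject agreement report: bias, RMSE, Pearson r, paired t-test.

    Pearson r is reported as NaN when either vector is constant (the
    correlation is undefined there).
    """
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape or truth.ndim != 1:
        raise ValidationError("truth and estimate must be 1-D of equal length")
    n = truth.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    diff = estimate - truth
    bias_mean = float(diff.mean())
    bias_sd = float(diff.std(ddof=1))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if truth.std() == 0 or estimate.std() == 0:
        r = float("nan")
    else:
        r = float(sps.pearsonr(truth, estimate).statistic)
    if bias_sd == 0:
        t_stat, p = 0.0, 1.0
    else:
        res = sps.ttest_rel(estimate, truth)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonReport(
        n=n,
        bias_mean_ms=bias_mean,
        bias_sd_ms=bias_sd,
        rmse_ms=rmse,
        pearson_r=r,
        t_statistic=t_stat,
        p_value=p,
        test_kind="paired",
    )


def group_ttest(
    group_a,
    group_b,
    kind: Literal["student", "welch"] = "student",
) -> tuple[float, float]:
    """Unpaired two-sample t-test; returns (t_score, two-sided p).

    The t-score sign follows (mean_a - mean_b)/SE, so calling with the
    low-risk group first gives positive scores when the healthier group has
    the higher feature value. Pooled-variance Student's test is the default;
    ``kind="welch"`` drops the equal-variance assumption.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValidationError("degenerate groups: zero variance, unequal means")
    res = sps.ttest_ind(a, b, equal_var=(kind == "student"))
    return float(res.statistic), float(res.pvalue)
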