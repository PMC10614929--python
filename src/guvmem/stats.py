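"""Statistical tests and summaries used for the GUV binding assays.

Student's (pooled-variance) two-sample t-test, one-way ANOVA, and mean/SD/SEM
summaries.  Welch's correction is available behind a flag but the pooled test
is the default.  Degenerate inputs (zero variance everywhere) follow
documented conventions: equal means give p = 1 two-tailed (0.5 one-tailed)
with t = 0, and an all-identical ANOVA gives F = 0, p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["StatResult", "unpaired_t_test", "one_way_anova", "mean_sd_sem"]


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    tails: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ParameterError("p-value outside [0, 1]")


def unpaired_t_test(
    x,
    y,
    tails: int = 2,
    alternative: str | None = None,
    welch: bool = False,
) -> StatResult:
    """Two-sample t-test; pooled variance (Student) unless ``welch``.

    ``tails=2`` tests a difference in either direction; ``tails=1`` tests the
    one-sided alternative (default ``'greater'``: mean(x) > mean(y)).  With
    zero variance in both groups and equal means the test is uninformative
    and returns t = 0 with p = 1 (two-tailed) or 0.5 (one-tailed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each group needs n >= 2")
    if tails not in (1, 2):
        raise ParameterError("tails must be 1 or 2")
    if tails == 2:
        alternative = "two-sided"
    elif alternative is None:
        alternative = "greater"
    elif alternative not in ("greater", "less"):
        raise ParameterError("one-tailed alternative must be 'greater' or 'less'")

    n1, n2 = x.size, y.size
    df = (n1 + n2 - 2) if not welch else None
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if welch:
            df = n1 + n2 - 2  # conventional fallback; Welch df undefined here
        if x.mean() == y.mean():
            return StatResult("t" if not welch else "welch-t", 0.0, float(df),
                              1.0 if tails == 2 else 0.5, tails)
        stat = np.inf * np.sign(x.mean() - y.mean())
        if tails == 2:
            p = 0.0
        else:
            good = (stat > 0) == (alternative == "greater")
            p = 0.0 if good else 1.0
        return StatResult("t" if not welch else "welch-t", float(stat), float(df), p, tails)

    res = sps.ttest_ind(x, y, equal_var=not welch, alternative=alternative)
    df = float(res.df)
    return StatResult(
        "t" if not welch else "welch-t",
        float(res.statistic),
        df,
        float(res.pvalue),
        tails,
    )


def one_way_anova(groups) -> StatResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    ``groups`` is an iterable of >= 2 samples, each with n >= 2.  All values
    identical gives F = 0, p = 1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ParameterError("each group needs n >= 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df = (float(k - 1), float(n_total - k))
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return StatResult("anova", 0.0, df, 1.0, 2)
    if all(np.var(a, ddof=1) == 0.0 for a in arrays):
        return StatResult("anova", float("inf"), df, 0.0, 2)
    res = sps.f_oneway(*arrays)
    return StatResult("anova", float(res.statistic), df, float(res.pvalue), 2)


def mean_sd_sem(values) -> tuple[float, float, float]:
    """Sample mean, SD (n-1 denominator) and SEM = SD / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("SD/SEM need n >= 2")
    sd = float(v.std(ddof=1))
    return float(v.mean()), sd, sd / np.sqrt(v.size)
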