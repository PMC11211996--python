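"""Statistical comparisons: Pearson correlation, Hotelling's test for two
dependent correlations sharing a variable, and the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value
    (t transform, n-2 degrees of freedom)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() < 1e-15 or y.std() < 1e-15:
        raise ValueError("constant input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationComparison:
    """Result of comparing two correlations that share a variable."""

    r_a: float
    r_b: float
    r_ab: float
    n: int
    t: float
    p: float

    def __post_init__(self) -> None:
        for r in (self.r_a, self.r_b, self.r_ab):
            if abs(r) > 1:
                raise ValueError("correlations must lie in [-1, 1]")
        if self.n < 4:
            raise ValueError("need n >= 4")


def hotelling_dependent(
    r_a: float, r_b: float, r_ab: float, n: int, williams: bool = False
) -> CorrelationComparison:
    """Hotelling's t-test for two dependent correlations sharing a variable.

    ``r_a`` and ``r_b`` correlate two predictors with the same outcome over
    ``n`` observations and ``r_ab`` is the correlation between the
    predictors.  The 1940 statistic is

        t = (r_a - r_b) sqrt((n - 3)(1 + r_ab)) / sqrt(2 |R|),

    with |R| = 1 - r_a^2 - r_b^2 - r_ab^2 + 2 r_a r_b r_ab, referred to
    Student's t with n - 3 df.  ``williams=True`` applies the Williams
    modification, which is less liberal for small n.
    """
    detR = 1 - r_a**2 - r_b**2 - r_ab**2 + 2 * r_a * r_b * r_ab
    if detR <= 0:
        raise ValueError("degenerate correlation triple (|R| <= 0)")
    if williams:
        rbar = (r_a + r_b) / 2
        denom = 2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r_ab) ** 3
        t = (r_a - r_b) * np.sqrt((n - 1) * (1 + r_ab) / denom)
    else:
        t = (r_a - r_b) * np.sqrt((n - 3) * (1 + r_ab)) / np.sqrt(2 * detR)
    p = 2 * scipy.stats.t.sf(abs(t), df=n - 3)
    return CorrelationComparison(r_a, r_b, r_ab, n, float(t), float(p))


def wilcoxon_signed_rank(pairs) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; W is the smaller of the positive- and
    negative-rank sums.  The p-value is exact for up to 25 nonzero
    differences and uses the normal approximation above that.
    """
    pairs = np.asarray(pairs, float)
    d = pairs[:, 0] - pairs[:, 1]
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    W = float(min(w_pos, w_neg))
    method = "exact" if d.size <= 25 else "approx"
    res = scipy.stats.wilcoxon(d, mode=method, alternative="two-sided")
    return W, float(res.pvalue)
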