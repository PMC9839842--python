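"""Group statistics: the one-tailed Welch (unequal-variances) t-test.

The test statistic is t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
Welch-Satterthwaite degrees of freedom; the one-tailed p-value is taken in
the direction of the stated alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "welch_one_tailed"]


@dataclass(frozen=True)
class TestResult:
    feature: str
    t_statistic: float
    dof: float
    p_one_tailed: float
    alternative: str
    n_a: int
    n_b: int

    def __post_init__(self):
        if not 0.0 < self.p_one_tailed < 1.0:
            raise ValueError("p-value must lie strictly in (0, 1)")
        if self.dof <= 0:
            raise ValueError("degrees of freedom must be positive")


def welch_one_tailed(group_a, group_b, alternative: str = "greater",
                     feature: str = "") -> TestResult:
    """One-tailed Welch t-test of mean(group_a) vs mean(group_b).

    ``alternative`` is "greater" (H1: mean_a > mean_b) or "less"
    (H1: mean_a < mean_b).  Sample variances use ddof=1.  Raises when both
    groups are degenerate (zero variance with equal means) since t is then
    undefined.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    se2 = va / len(a) + vb / len(b)
    if se2 == 0:
        raise ValueError("zero variance in both groups: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    dof = se2 ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    if alternative == "greater":
        p = float(sps.t.sf(t, dof))
    else:
        p = float(sps.t.cdf(t, dof))
    p = min(max(p, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))
    return TestResult(feature=feature, t_statistic=float(t), dof=float(dof),
                      p_one_tailed=p, alternative=alternative,
                      n_a=len(a), n_b=len(b))
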