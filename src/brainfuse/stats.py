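"""Paired-difference Student's-t comparison of two classifiers.

Two classifiers are compared across N experiment stages via the absolute
accuracy differences D_i = |acc_a,i - acc_b,i| (percentage points): the
statistic T = sqrt(N) * mean(D) / sd(D) (sample sd, N-1 denominator) is
checked against the two-tailed critical value at N-1 degrees of freedom.
The reported decision text mirrors the source framing, whose null
hypothesis is "there IS a significant difference between the
classifiers": a statistic inside the critical interval rejects it, i.e.
the classifiers are judged equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TTestResult", "paired_difference_test", "t_critical"]


@dataclass
class TTestResult:
    differences: np.ndarray
    mean: float
    sd: float
    t_selection: float
    df: int
    alpha: float
    critical: float
    within_interval: bool
    decision_text: str

    def to_dict(self) -> dict:
        return {
            "differences": self.differences.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "t_selection": self.t_selection,
            "df": self.df,
            "alpha": self.alpha,
            "critical": self.critical,
            "within_interval": self.within_interval,
            "decision_text": self.decision_text,
        }


def t_critical(df: int, alpha: float) -> float:
    """Two-tailed Student-t critical value (inverse CDF at 1 - alpha/2)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(sps.t.ppf(1.0 - alpha / 2.0, df))


def paired_difference_test(acc_a, acc_b, alpha: float = 0.05) -> TTestResult:
    """Paired absolute-difference t comparison of two accuracy vectors."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("accuracy vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two paired experiments")
    d = np.abs(a - b)
    mu = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ValueError(
            "all paired differences are equal; the t statistic is undefined")
    t = float(np.sqrt(n) * mu / sd)
    crit = t_critical(n - 1, alpha)
    within = bool(-crit <= t <= crit)
    if within:
        decision = ("T-Selection lies within the critical interval: the "
                    "hypothesis of a significant difference is rejected — "
                    "no significant difference between the classifiers.")
    else:
        decision = ("T-Selection lies outside the critical interval: the "
                    "classifiers differ significantly across experiments.")
    return TTestResult(differences=d, mean=mu, sd=sd, t_selection=t,
                       df=n - 1, alpha=float(alpha), critical=crit,
                       within_interval=within, decision_text=decision)
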