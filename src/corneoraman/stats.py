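"""Cohort statistics: paired t-tests between depths, normality, p grading.

Comparisons between adjacent normalised depths use the classical paired
Student t-test on per-volunteer values (two-sided; no directional hypothesis
is declared).  Normality of the paired differences is checked with the
Jarque-Bera statistic ``JB = n/6 (S^2 + K^2/4)`` (S sample skewness, K excess
kurtosis) against the chi-square(2) reference, which is asymptotic -- a
small-n caveat is flagged below n = 30.  p-values are graded with fixed
thresholds: <= 0.01 highly significant, <= 0.05 significant, <= 0.1 trend,
otherwise not significant.  No multiple-testing correction is applied to the
adjacent-depth comparisons; they are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import chi2, t as t_dist

from .exceptions import ValidationError

__all__ = ["GRADES", "StatResult", "paired_t", "jarque_bera", "grade_p"]

GRADES = ("highly significant", "significant", "trend", "not significant")


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p: float
    n: int
    grade: str
    flags: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0) and np.isfinite(self.p):
            raise ValidationError(f"p-value {self.p:g} outside [0, 1]")


def grade_p(p: float) -> str:
    """Grade a p-value; boundary values land in the stricter class."""
    if not np.isfinite(p) or p < 0 or p > 1:
        raise ValidationError(f"p-value must lie in [0, 1], got {p!r}")
    if p <= 0.01:
        return "highly significant"
    if p <= 0.05:
        return "significant"
    if p <= 0.1:
        return "trend"
    return "not significant"


def paired_t(values_a, values_b) -> StatResult:
    """Two-sided paired Student t-test on per-volunteer value pairs.

    Degenerate zero-variance differences are flagged: p = 1 for identically
    zero differences, p = 0 (with a warning flag) for a constant nonzero
    shift.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired t-test needs equal-length 1-D vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("missing pairs are not allowed")
    n = a.size
    if n < 3:
        raise ValidationError(f"paired t-test needs n >= 3, got {n}")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return StatResult("paired_t", 0.0, 1.0, n, grade_p(1.0),
                              ("degenerate:zero_differences",))
        return StatResult("paired_t", np.inf * np.sign(mean), 0.0, n, grade_p(0.0),
                          ("degenerate:zero_variance_nonzero_mean",))
    stat = mean / (sd / np.sqrt(n))
    p = float(2.0 * t_dist.sf(abs(stat), n - 1))
    return StatResult("paired_t", float(stat), p, n, grade_p(p))


def jarque_bera(values) -> StatResult:
    """Jarque-Bera normality test, JB = n/6 (S^2 + K^2/4), chi2(2) reference."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValidationError("Jarque-Bera needs a 1-D sample with n >= 8")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in sample")
    n = x.size
    xc = x - x.mean()
    m2 = float(np.mean(xc ** 2))
    if m2 == 0.0:
        raise ValidationError("constant input: skewness undefined")
    skew = float(np.mean(xc ** 3)) / m2 ** 1.5
    kurt = float(np.mean(xc ** 4)) / m2 ** 2 - 3.0
    jb = n / 6.0 * (skew ** 2 + kurt ** 2 / 4.0)
    p = float(chi2.sf(jb, 2))
    flags = ("small_n:asymptotic_p",) if n < 30 else ()
    return StatResult("jarque_bera", jb, p, n, grade_p(p), flags)
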