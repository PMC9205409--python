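"""Treatment cost function and paired comparison of dosing policies.

A treated course is scored by the per-visit average

    J = (1/N) * sum_i  a1*(x2(Ti) - r)^2 + a2*u(Ti)^2
                       + b1*h1(x2(Ti)) + b2*h2(x2(Ti))

with the one-sided penalties h1(x2) = (max(m, x2) - x2)^2 (hypothyroidism:
only FT4 below m contributes) and h2(x2) = (min(M, x2) - x2)^2
(hyperthyroidism: only FT4 above M contributes).  Lower J is better; J = 0
means every visit sat exactly on target with zero dose.

Three standard weight presets are provided: tracking only, tracking plus a
small dose penalty, and pure target-range violation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .control import TreatmentCourse
from .model import ValidationError

__all__ = ["CostWeights", "ComparisonReport", "cost", "preset_weights", "compare_policies", "PRESETS"]


@dataclass(frozen=True)
class CostWeights:
    """Weights and thresholds of the treatment cost functional."""

    alpha1: float  # tracking weight
    alpha2: float  # dose weight
    beta1: float  # hypothyroid penalty weight
    beta2: float  # hyperthyroid penalty weight
    m: float = 14.5  # pmol/L, FT4 below this is penalised by beta1
    M: float = 19.0  # pmol/L, FT4 above this is penalised by beta2
    r: float = 16.75  # pmol/L, tracking reference (=(24 + 9.5)/2)

    def __post_init__(self):
        if min(self.alpha1, self.alpha2, self.beta1, self.beta2) < 0:
            raise ValidationError("cost weights must be non-negative")
        if not self.m < self.M:
            raise ValidationError(f"need m < M, got m={self.m}, M={self.M}")


PRESETS = {
    # tracking performance only
    "tracking": CostWeights(alpha1=1.0, alpha2=0.0, beta1=0.0, beta2=0.0),
    # tracking plus a small penalty on MMI consumption
    "dosing_and_tracking": CostWeights(alpha1=1.0, alpha2=0.05, beta1=0.0, beta2=0.0),
    # pure target-range violation
    "target_range": CostWeights(alpha1=0.0, alpha2=0.0, beta1=1.0, beta2=1.0),
}


def preset_weights(name: str) -> CostWeights:
    """Return one of the named weight presets (see :data:`PRESETS`)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown cost preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def _h1(x2: np.ndarray, m: float) -> np.ndarray:
    return (np.maximum(m, x2) - x2) ** 2


def _h2(x2: np.ndarray, M: float) -> np.ndarray:
    return (np.minimum(M, x2) - x2) ** 2


def cost(course: TreatmentCourse, w: CostWeights) -> float:
    """Evaluate the cost functional on a treated course (mean over visits)."""
    x2 = np.asarray(course.ft4, dtype=float)
    u = np.asarray(course.doses, dtype=float)
    if x2.size < 1:
        raise ValidationError("treatment course has no visits")
    terms = (
        w.alpha1 * (x2 - w.r) ** 2
        + w.alpha2 * u**2
        + w.beta1 * _h1(x2, w.m)
        + w.beta2 * _h2(x2, w.M)
    )
    return float(terms.mean())


@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of two policies' per-patient costs."""

    test: str  # "paired_t" or "wilcoxon"
    statistic: float
    p_value: float
    mean_difference: float  # mean(a - b); positive means b is cheaper
    direction: str  # "b_lower" | "a_lower" | "no_difference"
    significant: bool  # at the 0.05 level
    normality_p: float | None  # Shapiro-Wilk p on the paired differences

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "mean_difference": float(self.mean_difference),
            "direction": self.direction,
            "significant": bool(self.significant),
            "normality_p": None if self.normality_p is None else float(self.normality_p),
        }


def compare_policies(
    costs_a: Sequence[float], costs_b: Sequence[float], alpha: float = 0.05
) -> ComparisonReport:
    """Paired test of two matched cost vectors.

    Differences are checked for normality (Shapiro-Wilk at 0.05); normal
    differences get a paired t-test, non-normal ones a Wilcoxon
    signed-rank test.  Two-sided p-values throughout.
    """
    a = np.asarray(costs_a, dtype=float)
    b = np.asarray(costs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("cost vectors must be matched 1-d arrays of equal length")
    if a.size < 5:
        raise ValidationError(f"paired comparison needs n >= 5, got {a.size}")
    d = a - b
    if np.allclose(d, 0.0):
        return ComparisonReport(
            test="paired_t",
            statistic=0.0,
            p_value=1.0,
            mean_difference=0.0,
            direction="no_difference",
            significant=False,
            normality_p=None,
        )
    if np.ptp(d) == 0.0:
        # a perfectly constant non-zero shift: degenerate for the normality
        # check, and the rank test handles it directly
        normality_p = 0.0
    else:
        normality_p = float(stats.shapiro(d).pvalue)
    if normality_p >= 0.05:
        res = stats.ttest_rel(a, b)
        test = "paired_t"
    else:
        res = stats.wilcoxon(a, b)
        test = "wilcoxon"
    p = float(res.pvalue)
    mean_d = float(d.mean())
    if p < alpha:
        direction = "b_lower" if mean_d > 0 else "a_lower"
    else:
        direction = "no_difference"
    return ComparisonReport(
        test=test,
        statistic=float(res.statistic),
        p_value=p,
        mean_difference=mean_d,
        direction=direction,
        significant=p < alpha,
        normality_p=normality_p,
    )
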