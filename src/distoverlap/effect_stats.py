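"""Classical two-sample comparison statistics and overlap decompositions.

Covers the statistics a practitioner would report alongside the overlap
index — pooled and Welch t tests and Cohen's d from group summaries — plus
two identities specific to the overlap:

* the complement delta = 1 - eta, equal to half the integrated absolute
  density difference (a dissimilarity measure);
* the misclassification split of eta into the two error masses of a
  Bayes-style classifier that assigns each point to the higher density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

from .kde import DensityEstimate, GridMismatchError, PairOverlap, Sample

__all__ = [
    "TwoSampleSummary",
    "TTestResult",
    "ErrorComponents",
    "pooled_sd",
    "cohens_d_pooled",
    "cohens_d_ci_normal_approx",
    "pooled_t",
    "welch_t",
    "complement_delta",
    "classification_error_components",
]


@dataclass(frozen=True)
class TwoSampleSummary:
    """Printed-style summary of two independent groups (mean, sd, n each)."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (self.sd_a > 0 and self.sd_b > 0):
            raise ValueError("group standard deviations must be > 0")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("group sizes must be >= 2")

    @classmethod
    def from_samples(cls, a: Sample, b: Sample) -> "TwoSampleSummary":
        return cls(
            mean_a=float(np.mean(a.values)),
            mean_b=float(np.mean(b.values)),
            sd_a=float(np.std(a.values, ddof=1)),
            sd_b=float(np.std(b.values, ddof=1)),
            n_a=a.n,
            n_b=b.n,
        )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class ErrorComponents:
    """Misclassification masses: err_a where f_A < f_B, err_b where f_B <= f_A."""

    err_a: float
    err_b: float

    @property
    def total(self) -> float:
        return self.err_a + self.err_b


def pooled_sd(s: TwoSampleSummary) -> float:
    """(n-1)-weighted two-sample pooled standard deviation."""
    num = (s.n_a - 1) * s.sd_a**2 + (s.n_b - 1) * s.sd_b**2
    return math.sqrt(num / (s.n_a + s.n_b - 2))


def cohens_d_pooled(s: TwoSampleSummary) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled sd, in input group order."""
    return (s.mean_a - s.mean_b) / pooled_sd(s)


def cohens_d_ci_normal_approx(
    s: TwoSampleSummary, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation confidence interval for Cohen's d.

    Uses the large-sample variance d^2/(2(n_a+n_b)) + (n_a+n_b)/(n_a*n_b).
    This is a documented approximation only; noncentral-t intervals differ
    in the second decimal at small n.
    """
    d = cohens_d_pooled(s)
    n_a, n_b = s.n_a, s.n_b
    se = math.sqrt(d * d / (2.0 * (n_a + n_b)) + (n_a + n_b) / (n_a * n_b))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    return (d - z * se, d + z * se)


def pooled_t(s: TwoSampleSummary) -> TTestResult:
    """Classical equal-variance two-sample t test from group summaries."""
    df = s.n_a + s.n_b - 2
    se = pooled_sd(s) * math.sqrt(1.0 / s.n_a + 1.0 / s.n_b)
    stat = (s.mean_a - s.mean_b) / se
    return TTestResult(stat, float(df), _two_sided_p(stat, df))


def welch_t(s: TwoSampleSummary) -> TTestResult:
    """Welch two-sample t test with Satterthwaite degrees of freedom."""
    va, vb = s.sd_a**2 / s.n_a, s.sd_b**2 / s.n_b
    se = math.sqrt(va + vb)
    stat = (s.mean_a - s.mean_b) / se
    df = (va + vb) ** 2 / (va**2 / (s.n_a - 1) + vb**2 / (s.n_b - 1))
    return TTestResult(stat, float(df), _two_sided_p(stat, df))


def _two_sided_p(stat: float, df: float) -> float:
    return float(2.0 * t_dist.sf(abs(stat), df))


def complement_delta(p: PairOverlap | float) -> float:
    """Dissimilarity complement delta = 1 - eta."""
    eta = p.eta if isinstance(p, PairOverlap) else float(p)
    return 1.0 - eta


def classification_error_components(
    dens_a: DensityEstimate, dens_b: DensityEstimate
) -> ErrorComponents:
    """Split the overlap into the two classification error masses.

    err_a is the mass of f_A on the region where f_A < f_B (choosing B when
    A is true); err_b is the mass of f_B where f_B <= f_A, with tie mass
    assigned to err_b. The two components sum to the overlap exactly,
    because min(f_A, f_B) = f_A*1[f_A < f_B] + f_B*1[f_B <= f_A] pointwise.
    """
    if not np.array_equal(dens_a.grid.points, dens_b.grid.points):
        raise GridMismatchError("error components require a shared grid")
    z = dens_a.grid.points
    fa, fb = dens_a.ordinates, dens_b.ordinates
    err_a = float(np.trapezoid(np.where(fa < fb, fa, 0.0), z))
    err_b = float(np.trapezoid(np.where(fb <= fa, fb, 0.0), z))
    return ErrorComponents(err_a=err_a, err_b=err_b)
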