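"""Closed-form overlap for Normal distributions and a brute-force oracle.

For two Normals with a common standard deviation sigma the overlap has the
closed form

    eta = 2 * Phi(-|mu_A - mu_B| / (2 * sigma)),

where the argument |mu_A - mu_B| / (2 sigma) is half the standardized mean
difference (Cohen's d), so eta is a strictly decreasing function of |d|.
The general unequal-variance Normal case is handled analytically through
the crossing points of the two density curves, and a fine-grid numeric
min-integral is provided as an independent oracle for arbitrary densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

__all__ = [
    "NormalParams",
    "normal_overlap_equal_sd",
    "overlap_from_cohens_d",
    "normal_overlap_general",
    "numeric_overlap_oracle",
]


@dataclass(frozen=True)
class NormalParams:
    """Location and scale of one Normal distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def normal_overlap_equal_sd(mu_a: float, mu_b: float, sigma: float) -> float:
    """Overlap of N(mu_a, sigma^2) and N(mu_b, sigma^2): 2*Phi(-|mu_a-mu_b|/(2*sigma))."""
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return float(2.0 * norm.cdf(-abs(mu_a - mu_b) / (2.0 * sigma)))


def overlap_from_cohens_d(d: float) -> float:
    """Overlap implied by a standardized mean difference: 2*Phi(-|d|/2)."""
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    return float(2.0 * norm.cdf(-abs(d) / 2.0))


def _normal_crossings(a: NormalParams, b: NormalParams) -> np.ndarray:
    """Real roots of f_a(x) = f_b(x), from the log-density difference quadratic."""
    if a.sigma == b.sigma:
        if a.mu == b.mu:
            return np.array([])
        return np.array([0.5 * (a.mu + b.mu)])
    # log f_a - log f_b is quadratic: c2 x^2 + c1 x + c0
    va, vb = a.sigma**2, b.sigma**2
    c2 = 0.5 * (1.0 / vb - 1.0 / va)
    c1 = a.mu / va - b.mu / vb
    c0 = (
        0.5 * (b.mu**2 / vb - a.mu**2 / va)
        + math.log(b.sigma / a.sigma)
    )
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc < 0:
        return np.array([])
    r = math.sqrt(disc)
    return np.sort(np.array([(-c1 - r) / (2.0 * c2), (-c1 + r) / (2.0 * c2)]))


def normal_overlap_general(a: NormalParams, b: NormalParams) -> float:
    """Exact overlap of two Normals with arbitrary means and standard deviations.

    The real line is split at the analytic crossing points of the two
    densities; on each piece the pointwise minimum is one of the two
    Normals, whose CDF mass is accumulated.
    """
    if (a.mu, a.sigma) == (b.mu, b.sigma):
        return 1.0
    cuts = _normal_crossings(a, b)
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        # probe which density is smaller on this piece
        if np.isinf(lo) and np.isinf(hi):
            probe = 0.5 * (a.mu + b.mu)
        elif np.isinf(lo):
            probe = hi - 1.0
        elif np.isinf(hi):
            probe = lo + 1.0
        else:
            probe = 0.5 * (lo + hi)
        fa = norm.pdf(probe, a.mu, a.sigma)
        fb = norm.pdf(probe, b.mu, b.sigma)
        p = (a.mu, a.sigma) if fa <= fb else (b.mu, b.sigma)
        total += norm.cdf(hi, *p) - norm.cdf(lo, *p)
    return float(min(1.0, max(0.0, total)))


def numeric_overlap_oracle(
    pdf_a: Callable[[np.ndarray], np.ndarray],
    pdf_b: Callable[[np.ndarray], np.ndarray],
    lower: float,
    upper: float,
    npoints: int = 1_000_000,
) -> float:
    """Brute-force overlap: trapezoidal min-integral on a fine uniform grid.

    Intended as a test oracle for known densities; ``[lower, upper]`` must
    carry essentially all the mass of both.
    """
    if npoints < 100_000:
        raise ValueError("npoints must be at least 1e5 for oracle accuracy")
    x = np.linspace(lower, upper, npoints)
    return float(np.trapezoid(np.minimum(pdf_a(x), pdf_b(x)), x))
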