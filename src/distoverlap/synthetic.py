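"""Seeded synthetic data generators for every overlap workflow stage.

Four scenarios are emulated, each mirroring a situation where the overlap
index is informative and classical mean tests are not the whole story:

* ``exam_scores`` — two modest-sized groups with equal means/sds on paper
  but one visibly right-skewed distribution;
* ``skewed_groups`` — two shifted-Gamma groups with unequal variances and
  skewness (a Welch-test setting);
* ``bootstrap_params`` — two approximately Normal bootstrap replicate
  vectors of a mediation indirect effect, one per group;
* ``prior_posterior`` — draws from a Normal prior and from its conjugate
  Normal posterior after a small dataset.

All generators are deterministic given the seed, and each has an analytic
population oracle (via :mod:`distoverlap.closed_form`) used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .closed_form import NormalParams
from .kde import Sample

__all__ = [
    "FixtureSpec",
    "GammaMoments",
    "skewed_group_params",
    "make_skewed_groups",
    "make_exam_scores",
    "make_bootstrap_param_pair",
    "conjugate_posterior",
    "make_prior_posterior",
    "generate",
]

SCENARIOS = ("exam_scores", "skewed_groups", "bootstrap_params", "prior_posterior")


@dataclass(frozen=True)
class FixtureSpec:
    """Which scenario to generate, with seed and per-group sizes."""

    scenario: str
    seed: int = 0
    sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class GammaMoments:
    """Shifted-Gamma parameterization matching a (mean, sd, skewness) target.

    For Gamma(shape k, scale theta), skewness = 2/sqrt(k) and sd =
    sqrt(k)*theta, so the target moments pin down (k, theta) and the shift.
    """

    mean: float
    sd: float
    skewness: float
    shape: float = field(init=False)
    scale: float = field(init=False)
    shift: float = field(init=False)

    def __post_init__(self) -> None:
        k = (2.0 / self.skewness) ** 2
        theta = self.sd / np.sqrt(k)
        object.__setattr__(self, "shape", k)
        object.__setattr__(self, "scale", theta)
        object.__setattr__(self, "shift", self.mean - k * theta)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.shift + rng.gamma(self.shape, self.scale, size=n)


# population targets for the two-skewed-groups scenario:
# group a: mean 1.57, sd 1.78, skewness 1.41; group b: mean 3.44, sd 4.32, skewness 1.93
_SKEWED_A = GammaMoments(mean=1.57, sd=1.78, skewness=1.41)
_SKEWED_B = GammaMoments(mean=3.44, sd=4.32, skewness=1.93)


def skewed_group_params() -> tuple[GammaMoments, GammaMoments]:
    """Population parameters of the two skewed-group generators."""
    return _SKEWED_A, _SKEWED_B


def make_skewed_groups(
    seed: int, n_a: int = 35, n_b: int = 30
) -> tuple[Sample, Sample]:
    """Two shifted-Gamma groups with unequal spread and skewness."""
    if n_a < 30 or n_b < 30:
        raise ValueError("skewed-group sizes must be >= 30")
    rng = np.random.default_rng(seed)
    return (
        Sample("x", _SKEWED_A.draw(rng, n_a)),
        Sample("y", _SKEWED_B.draw(rng, n_b)),
    )


def make_exam_scores(
    seed: int, n_male: int = 22, n_female: int = 59
) -> tuple[Sample, Sample]:
    """Exam-score-like groups: right-skewed males, near-symmetric females.

    Group means and sds target (17.05, 6.28) and (18.54, 6.27); the male
    group is drawn from a shifted Gamma with skewness 1.0 and the female
    group from a Normal.
    """
    rng = np.random.default_rng(seed)
    male = GammaMoments(mean=17.05, sd=6.28, skewness=1.0)
    return (
        Sample("male", male.draw(rng, n_male)),
        Sample("female", rng.normal(18.54, 6.27, size=n_female)),
    )


# printed-style indirect-effect estimates: 0.23 (se 0.15) males, 0.62 (se 0.26) females
_INDIRECT_M = NormalParams(mu=0.23, sigma=0.15)
_INDIRECT_F = NormalParams(mu=0.62, sigma=0.26)


def make_bootstrap_param_pair(seed: int, B: int = 1000) -> tuple[Sample, Sample]:
    """Emulated bootstrap replicate vectors of an indirect effect, by group.

    Bootstrap distributions of a maximum-likelihood estimate are
    approximately Normal around the estimate with sd equal to its standard
    error, so the replicates are drawn from N(0.23, 0.15^2) and
    N(0.62, 0.26^2).  The population overlap oracle is
    ``normal_overlap_general`` on those two Normals.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    rng = np.random.default_rng(seed)
    return (
        Sample("male", rng.normal(_INDIRECT_M.mu, _INDIRECT_M.sigma, size=B)),
        Sample("female", rng.normal(_INDIRECT_F.mu, _INDIRECT_F.sigma, size=B)),
    )


def conjugate_posterior(
    prior: NormalParams,
    data_mean: float,
    data_sd: float,
    data_n: int,
) -> NormalParams:
    """Normal-Normal conjugate update for a mean with known data sd."""
    prior_prec = 1.0 / prior.sigma**2
    data_prec = data_n / data_sd**2
    post_var = 1.0 / (prior_prec + data_prec)
    post_mean = post_var * (prior_prec * prior.mu + data_prec * data_mean)
    return NormalParams(mu=post_mean, sigma=float(np.sqrt(post_var)))


def make_prior_posterior(
    seed: int,
    prior_sd: float = 0.32,
    n_draws: int = 4000,
    prior_mean: float = 0.5,
    data_mean: float = 0.75,
    data_sd: float = 1.05,
    data_n: int = 10,
) -> tuple[Sample, Sample]:
    """Draws from a Normal(prior_mean, prior_sd) prior and its conjugate posterior.

    The posterior is the analytic Normal-Normal update against a small
    dataset (default: 10 observations with mean 0.75 and declared sd 1.05),
    so the population prior/posterior overlap is available in closed form.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    prior = NormalParams(mu=prior_mean, sigma=prior_sd)
    post = conjugate_posterior(prior, data_mean, data_sd, data_n)
    rng = np.random.default_rng(seed)
    return (
        Sample("prior", rng.normal(prior.mu, prior.sigma, size=n_draws)),
        Sample("posterior", rng.normal(post.mu, post.sigma, size=n_draws)),
    )


def generate(spec: FixtureSpec) -> tuple[Sample, ...]:
    """Dispatch a :class:`FixtureSpec` to its generator."""
    if spec.scenario == "exam_scores":
        return make_exam_scores(spec.seed, *spec.sizes)
    if spec.scenario == "skewed_groups":
        return make_skewed_groups(spec.seed, *spec.sizes)
    if spec.scenario == "bootstrap_params":
        return make_bootstrap_param_pair(spec.seed, *spec.sizes)
    return make_prior_posterior(spec.seed)
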