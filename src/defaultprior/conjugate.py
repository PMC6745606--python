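"""Exact normal-normal conjugate inference under the default shrinkage prior.

The model: an approximately unbiased, normal estimator ``B`` of a regression
coefficient ``beta`` with known standard error ``se``, combined with the
zero-mean normal prior ``beta ~ N(0, g * se**2)``.  The default ``g = 1``
makes the prior standard deviation equal to the standard error, which is the
unique normal prior under which the posterior sign probability
``P(beta > 0 | B)`` is uniformly distributed (see :mod:`defaultprior.sign`).

All quantities here are closed-form in the standard normal CDF; no Monte
Carlo is used in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy.stats import norm

__all__ = [
    "Estimate",
    "ShrinkagePrior",
    "PosteriorNormal",
    "ConflictAssessment",
    "shrink_posterior",
    "sign_probability",
    "credible_interval",
    "conditional_coverage",
    "coverage_vs_pvalue",
    "p_to_absz",
    "implied_se",
    "prior_tail_flag",
    "CONFLICT_P_THRESHOLD",
]

#: Two-sided p-value below which the default prior is in conflict with the
#: data and should not be used.
CONFLICT_P_THRESHOLD = 0.001


@dataclass(frozen=True)
class Estimate:
    """An observed coefficient estimate ``b`` with its standard error ``se``."""

    b: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.b):
            raise ValueError(f"estimate b must be finite, got {self.b}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"standard error must be positive, got {self.se}")


@dataclass(frozen=True)
class ShrinkagePrior:
    """Zero-mean normal prior with variance ``g * se**2``.

    ``g`` is the ratio of the prior variance to the squared standard error.
    The default ``g = 1`` gives prior standard deviation equal to ``se``.
    """

    g: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g) and self.g > 0):
            raise ValueError(f"prior variance ratio g must be positive, got {self.g}")

    @property
    def shrinkage_factor(self) -> float:
        """Multiplier ``g / (g + 1)`` taking the estimate to the posterior mean."""
        return self.g / (self.g + 1.0)


@dataclass(frozen=True)
class PosteriorNormal:
    """Normal posterior with explicit mean and standard deviation.

    At ``g = 1`` this is ``N(b/2, se**2 / 2)``: posterior mean half the
    estimate and posterior standard deviation ``se / sqrt(2)``.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"posterior sd must be positive, got {self.sd}")

    def cdf(self, x: float) -> float:
        return float(norm.cdf(x, loc=self.mean, scale=self.sd))


class ConflictAssessment(NamedTuple):
    """Result of the prior-data-conflict check on a two-sided p-value."""

    flagged: bool
    tail_probability: float


def shrink_posterior(est: Estimate, prior: ShrinkagePrior = ShrinkagePrior()) -> PosteriorNormal:
    """Posterior of ``beta`` given ``B = b`` under the ``N(0, g*se^2)`` prior.

    Standard conjugate algebra gives

    .. math:: \\beta \\mid B=b \\sim N\\!\\Big(\\frac{g}{g+1} b,\\;
              \\frac{g}{g+1} se^2\\Big).

    At ``g = 1`` the posterior is ``N(b/2, se^2/2)``, i.e. the estimate is
    shrunk halfway to zero and the posterior sd is ``se / sqrt(2)``.
    """
    w = prior.shrinkage_factor
    return PosteriorNormal(mean=w * est.b, sd=est.se * math.sqrt(w))


def sign_probability(est: Estimate, prior: ShrinkagePrior = ShrinkagePrior()) -> float:
    """Posterior probability that the coefficient is positive.

    ``P(beta > 0 | B=b) = Phi(posterior mean / posterior sd)``; at ``g = 1``
    this is ``Phi(b / (sqrt(2) * se))``.  The complement rule
    ``P(beta < 0 | B=b) = 1 - P(beta > 0 | B=b)`` holds exactly because the
    posterior is continuous.
    """
    post = shrink_posterior(est, prior)
    return float(norm.cdf(post.mean / post.sd))


def credible_interval(
    est: Estimate,
    prior: ShrinkagePrior = ShrinkagePrior(),
    level: float = 0.95,
) -> tuple[float, float]:
    """Central posterior credible interval at the given level.

    Returns ``posterior mean +/- z_{(1+level)/2} * posterior sd``.  At
    ``g = 1`` and level 0.95 this is ``b/2 +/- 1.96 * se/sqrt(2)``, which by
    construction carries exactly 95% posterior mass.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"credible level must be in (0, 1), got {level}")
    post = shrink_posterior(est, prior)
    z = float(norm.ppf(0.5 * (1.0 + level)))
    return (post.mean - z * post.sd, post.mean + z * post.sd)


def conditional_coverage(
    est: Estimate,
    prior: ShrinkagePrior = ShrinkagePrior(),
    level: float = 0.95,
) -> float:
    """Posterior probability that beta lies in the standard Wald interval.

    The Wald interval ``[b - z*se, b + z*se]`` (``z = 1.96`` at level 0.95)
    has long-run frequentist coverage ``level`` for every fixed beta, but its
    *conditional* coverage given the observed ``b`` depends on ``b``.  Under
    the ``g = 1`` prior it equals

    .. math:: \\Phi\\Big(\\frac{b}{\\sqrt{2}\\,se} + 1.96\\sqrt{2}\\Big)
              - \\Phi\\Big(\\frac{b}{\\sqrt{2}\\,se} - 1.96\\sqrt{2}\\Big),

    which declines from about 0.994 at ``b = 0`` toward zero as ``|b|`` grows:
    the more significant the estimate, the worse the Wald interval performs as
    a credible interval.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = float(norm.ppf(0.5 * (1.0 + level)))
    post = shrink_posterior(est, prior)
    lo, hi = est.b - z * est.se, est.b + z * est.se
    return float(norm.cdf((hi - post.mean) / post.sd) - norm.cdf((lo - post.mean) / post.sd))


def coverage_vs_pvalue(
    p: float,
    prior: ShrinkagePrior = ShrinkagePrior(),
    se: float = 1.0,
    level: float = 0.95,
) -> float:
    """Conditional Wald coverage as a function of the two-sided p-value.

    Maps ``p`` to ``|b|/se = |Phi^{-1}(p/2)|`` and evaluates
    :func:`conditional_coverage`.  Monotone increasing in ``p`` at ``g = 1``:
    smaller p-values (stronger apparent significance) mean lower conditional
    coverage.
    """
    absz = p_to_absz(p)
    return conditional_coverage(Estimate(b=absz * se, se=se), prior, level=level)


def p_to_absz(p: float) -> float:
    """Absolute z-value corresponding to a two-sided p-value.

    Solves ``2 * Phi(-|z|) = p``:  ``|z| = |Phi^{-1}(p/2)| = Phi^{-1}(1 - p/2)``.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"two-sided p-value must be in (0, 1], got {p}")
    return float(norm.isf(p / 2.0))


def implied_se(b: float, p: float) -> float:
    """Implied standard error ``|b| / |z|`` reconstructed from ``b`` and ``p``.

    Useful when a paper reports an estimate and a p-value but not the
    standard error.  Undefined at ``b = 0`` or ``p >= 1`` (where ``|z| = 0``).
    """
    if b == 0:
        raise ValueError("implied standard error is undefined for b = 0")
    if not (0.0 < p < 1.0):
        raise ValueError(f"implied standard error needs p in (0, 1), got {p}")
    return abs(b) / p_to_absz(p)


def prior_tail_flag(p: float, prior: ShrinkagePrior = ShrinkagePrior()) -> ConflictAssessment:
    """Prior-data-conflict check: is the observed p-value implausible a priori?

    Under the ``N(0, g*se^2)`` prior the marginal distribution of
    ``Z = B/se`` is ``N(0, g+1)``, so the prior predictive probability of
    observing ``|Z| > 3.29`` (two-sided p below 0.001) is
    ``2 * Phi(-3.29 / sqrt(g+1))`` -- about 2% at ``g = 1``.  A p-value below
    0.001 is therefore flagged: the default prior should not be used there.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"two-sided p-value must be in (0, 1], got {p}")
    z_threshold = p_to_absz(CONFLICT_P_THRESHOLD)
    tail = float(2.0 * norm.cdf(-z_threshold / math.sqrt(prior.g + 1.0)))
    return ConflictAssessment(flagged=p < CONFLICT_P_THRESHOLD, tail_probability=tail)
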