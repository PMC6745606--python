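"""Folded-normal machinery for magnitude (type-M) inference.

If ``X ~ N(mu, sigma^2)`` then ``|X|`` has the folded normal distribution
with mean

.. math:: E|X| = |\\mu| + \\sqrt{2/\\pi}\\,\\sigma\\,e^{-\\mu^2/2\\sigma^2}
          - 2|\\mu|\\,\\Phi(-|\\mu|/\\sigma).

Two readings of this formula matter here.  Frequentist: ``|B|`` is positively
biased for ``|beta|`` (Jensen), maximally so at ``beta = 0`` where the bias
is ``sqrt(2/pi) * se ~ 0.8 se``.  Bayesian: under the flat prior the
posterior of ``beta`` given ``B = b`` is ``N(b, se^2)``, so the flat-prior
Bayes estimate of ``|beta|`` under squared error loss is the same folded
mean evaluated at ``mu = b`` -- even larger than ``|b|``.  The shrinkage
posterior replaces ``(b, se)`` with the shrunk mean and reduced sd, giving a
smaller magnitude estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .conjugate import Estimate, ShrinkagePrior, shrink_posterior

__all__ = [
    "FoldedNormalSpec",
    "folded_mean",
    "magnitude_bias",
    "flat_posterior_magnitude_mean",
    "shrunk_posterior_magnitude_mean",
]

# Beyond this many sds from zero both correction terms underflow double
# precision; return |mu| directly.
_SEPARATION_RATIO = 38.0


@dataclass(frozen=True)
class FoldedNormalSpec:
    """Parameters of the underlying normal whose absolute value is folded."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")


def folded_mean(spec: FoldedNormalSpec) -> float:
    """Mean of ``|X|`` for ``X ~ N(mu, sigma^2)``.

    Always at least ``|mu|`` (Jensen's inequality), with equality only in
    the ``sigma -> 0`` limit.
    """
    a = abs(spec.mu)
    s = spec.sigma
    r = a / s
    if r > _SEPARATION_RATIO:
        return a
    return a + math.sqrt(2.0 / math.pi) * s * math.exp(-0.5 * r * r) - 2.0 * a * float(norm.cdf(-r))


def magnitude_bias(beta: float, se: float) -> float:
    """Frequentist bias ``E_beta |B| - |beta|`` of ``|B|`` as an estimator of ``|beta|``.

    Nonnegative everywhere; maximal at ``beta = 0`` where it equals
    ``sqrt(2/pi) * se``, roughly ``0.8 se``.
    """
    return folded_mean(FoldedNormalSpec(mu=beta, sigma=se)) - abs(beta)


def flat_posterior_magnitude_mean(est: Estimate) -> float:
    """Flat-prior posterior mean of ``|beta|`` given ``B = b``.

    The flat-prior posterior of ``beta`` is ``N(b, se^2)``, so this is the
    folded-normal mean at ``(b, se)``; it exceeds ``|b|``, which is itself
    already positively biased for ``|beta|``.
    """
    return folded_mean(FoldedNormalSpec(mu=est.b, sigma=est.se))


def shrunk_posterior_magnitude_mean(
    est: Estimate, prior: ShrinkagePrior = ShrinkagePrior()
) -> float:
    """Posterior mean of ``|beta|`` under the ``N(0, g*se^2)`` shrinkage prior.

    The shrinkage posterior is normal, so the folded-normal mean applies
    exactly with the posterior mean and sd in place of ``(b, se)``.  At
    ``g = 1`` this never exceeds the flat-prior magnitude estimate.
    """
    post = shrink_posterior(est, prior)
    return folded_mean(FoldedNormalSpec(mu=post.mean, sigma=post.sd))
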