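"""Numeric Jeffreys prior for the magnitude ``theta = |beta|`` under a
sign-mixture likelihood.

Reparameterizing the normal location model in terms of sign and magnitude
(with a Bernoulli(1/2) prior on the sign) turns the distribution of the
estimator ``B`` into a two-component normal mixture

.. math:: f(b \\mid \\theta) = \\tfrac{1}{2se}\\,\\phi\\big((b+\\theta)/se\\big)
          + \\tfrac{1}{2se}\\,\\phi\\big((b-\\theta)/se\\big).

The Jeffreys prior on ``theta`` is proportional to the square root of the
Fisher information of this mixture, which has no closed form but is cheap to
compute by quadrature.  The information is zero at ``theta = 0`` (the two
components coincide and the score vanishes identically) and approaches the
location-model information ``1/se^2`` once the components separate
(``theta`` beyond a few ``se``), so the prior rises from zero and flattens
-- it is *more* dispersed than uniform, not less.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "MixtureModel",
    "JeffreysGrid",
    "mixture_density",
    "score_theta",
    "fisher_info",
    "jeffreys_grid",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureModel:
    """Sign-mixture model for the estimator of a coefficient of magnitude theta."""

    theta: float
    se: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta) and self.theta >= 0):
            raise ValueError(f"theta = |beta| must be nonnegative, got {self.theta}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be positive, got {self.se}")


def _phi(x: np.ndarray | float) -> np.ndarray | float:
    return np.exp(-0.5 * np.square(x)) / _SQRT2PI


def mixture_density(b: np.ndarray | float, model: MixtureModel) -> np.ndarray | float:
    """Density of ``B`` given ``theta``: equal mixture of ``N(+-theta, se^2)``.

    Symmetric in ``b``; collapses to the ``N(0, se^2)`` density at
    ``theta = 0``.
    """
    t, se = model.theta, model.se
    return (_phi((np.asarray(b) + t) / se) + _phi((np.asarray(b) - t) / se)) / (2.0 * se)


def score_theta(b: np.ndarray | float, model: MixtureModel) -> np.ndarray | float:
    """Exact score ``d/dtheta log f(b | theta)`` of the sign mixture.

    .. math:: \\frac{-(b+\\theta)\\phi((b+\\theta)/se)
              + (b-\\theta)\\phi((b-\\theta)/se)}
              {se^2\\,[\\phi((b+\\theta)/se) + \\phi((b-\\theta)/se)]}

    The ``1/se^2`` constant is fixed by differentiation (it matters because
    the Fisher information squares the score).  Identically zero at
    ``theta = 0``, and even in ``b`` (the mixture density is even in ``b``,
    so every theta-derivative of its logarithm is too).
    """
    t, se = model.theta, model.se
    b = np.asarray(b, dtype=float)
    # the common factor exp(-(b^2+t^2)/2se^2)/sqrt(2pi) cancels between
    # numerator and denominator; rescale by exp(-|bt|/se^2) so neither
    # surviving exponential can overflow
    c = b * t / se**2
    ep = np.exp(-c - np.abs(c))  # ~ phi((b+t)/se) up to common factors
    em = np.exp(c - np.abs(c))  # ~ phi((b-t)/se) likewise
    num = -(b + t) * ep + (b - t) * em
    den = se**2 * (ep + em)
    out = num / den
    return out if out.ndim else float(out)


def fisher_info(model: MixtureModel, epsabs: float = 1e-9) -> float:
    """Fisher information ``E_theta[score^2]`` of the sign mixture, by quadrature.

    Integrates ``score^2 * f(b|theta)`` over ``|b| <= theta + 10 se`` (the
    neglected tail mass is far below the tolerance).  Satisfies
    ``0 <= I(theta) <= 1/se^2``: sign uncertainty can only lose information
    relative to the plain location model, and the loss is total at
    ``theta = 0``.
    """
    t, se = model.theta, model.se
    if t == 0.0:
        return 0.0
    lim = t + 10.0 * se

    def integrand(b: float) -> float:
        s = score_theta(b, model)
        return float(s * s * mixture_density(b, model))

    val, err = integrate.quad(
        integrand, -lim, lim, points=[-t, 0.0, t], epsabs=epsabs, limit=400
    )
    if err > max(100.0 * epsabs, 1e-6 * abs(val)):
        raise ArithmeticError(
            f"Fisher-information quadrature did not converge at theta={t}, se={se}: "
            f"value={val:.6e}, error estimate={err:.2e}"
        )
    return max(0.0, val)


@dataclass(frozen=True)
class JeffreysGrid:
    """Unnormalized Jeffreys prior ``sqrt(I(theta))`` tabulated on a theta grid.

    The prior is improper on ``[0, inf)`` (constant positive tail), so the
    values are reported up to proportionality only; normalize to a maximum of
    one for display if desired.
    """

    theta_grid: np.ndarray
    values: np.ndarray
    se: float


def jeffreys_grid(theta_max: float, n_points: int, se: float) -> JeffreysGrid:
    """Evaluate the unnormalized Jeffreys prior on a uniform grid over [0, theta_max].

    ``values[0]`` (at ``theta = 0``) is exactly zero; the values rise
    monotonically and approach ``1/se`` as ``theta`` grows past a few ``se``.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if not (math.isfinite(theta_max) and theta_max > 0):
        raise ValueError(f"theta_max must be positive, got {theta_max}")
    thetas = np.linspace(0.0, theta_max, n_points)
    vals = np.array([math.sqrt(fisher_info(MixtureModel(theta=float(t), se=se))) for t in thetas])
    return JeffreysGrid(theta_grid=thetas, values=vals, se=se)
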