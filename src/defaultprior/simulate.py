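"""Synthetic study collections and single-estimate draws.

Two generators.  :func:`simulate_zdataset` draws from the hierarchical model
used for empirical-Bayes estimation of ``g``: study effects
``g_j ~ N(g, sigma^2)`` (truncated to ``g_j >= 0`` by rejection -- a
negative prior variance cannot be simulated from), then z-values
``Z_ij ~ N(0, g_j + 1)``, returned as squared z-values grouped by study.
:func:`simulate_estimates` draws ``(beta, B)`` pairs from the single-level
model ``beta ~ N(0, g*se^2)``, ``B | beta ~ N(beta, se^2)`` for coverage and
sign simulations.

The default design mirrors a realistic meta-analytic harvest: 50 articles
with about 12 usable p-values each.  The default between-study sd
``sigma = 0.5`` produces visible but moderate heterogeneity in the
z-value spread across articles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ebayes import ZDataset

__all__ = ["SimConfig", "EstimateDraws", "simulate_zdataset", "simulate_estimates"]

DEFAULT_N_STUDIES = 50
DEFAULT_N_PER_STUDY = 12
DEFAULT_SIGMA = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic study collection."""

    n_studies: int = DEFAULT_N_STUDIES
    n_per_study: "int | tuple[int, ...]" = DEFAULT_N_PER_STUDY
    g: float = 1.0
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError(f"n_studies must be >= 1, got {self.n_studies}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        counts = self.counts()
        if len(counts) != self.n_studies or any(c < 1 for c in counts):
            raise ValueError("n_per_study must give a count >= 1 for every study")
        if self.sigma == 0.0 and self.g < 0:
            raise ValueError("g < 0 with sigma = 0 leaves no nonnegative study effects")

    def counts(self) -> "tuple[int, ...]":
        if isinstance(self.n_per_study, int):
            return (self.n_per_study,) * self.n_studies
        return tuple(self.n_per_study)


def simulate_zdataset(config: SimConfig) -> "tuple[ZDataset, float]":
    """Draw a study collection under the hierarchical model.

    Returns the dataset and the rejection rate of the ``g_j >= 0``
    truncation (the fraction of raw Gaussian draws discarded; small for
    ``g`` around 1 and ``sigma`` below about 0.6).
    """
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    accepted: list[float] = []
    n_consumed = 0
    while len(accepted) < config.n_studies:
        draws = config.g + config.sigma * rng.standard_normal(config.n_studies)
        ok = draws >= 0.0
        if config.sigma == 0.0 and not ok.any():
            raise ValueError("g < 0 with sigma = 0: no feasible study effects")
        need = config.n_studies - len(accepted)
        cum = np.cumsum(ok)
        if cum[-1] >= need:
            # stop at the draw that completes the sample, so the rejection
            # rate reflects only the draws actually consumed
            stop = int(np.searchsorted(cum, need)) + 1
            accepted.extend(draws[:stop][ok[:stop]])
            n_consumed += stop
        else:
            accepted.extend(draws[ok])
            n_consumed += draws.size
    g_j = np.asarray(accepted)
    rejection_rate = 1.0 - config.n_studies / n_consumed

    sids = np.repeat([f"study{j:03d}" for j in range(config.n_studies)], counts)
    sd = np.repeat(np.sqrt(g_j + 1.0), counts)
    z = rng.standard_normal(sd.size) * sd
    return ZDataset(study_ids=sids, z2=np.square(z)), rejection_rate


@dataclass(frozen=True)
class EstimateDraws:
    """Joint draws of true coefficients and their estimates."""

    beta: np.ndarray
    b: np.ndarray
    se: np.ndarray


def simulate_estimates(
    n: int, g: float = 1.0, se_values: "float | list[float]" = 1.0, seed: int = 0
) -> EstimateDraws:
    """Draw ``(beta, B)`` pairs from ``beta ~ N(0, g*se^2)``, ``B|beta ~ N(beta, se^2)``.

    ``se_values`` may be a scalar or a list cycled over the ``n`` draws.
    Marginally the Wald interval ``B +/- 1.96 se`` covers beta 95% of the
    time (the frequentist statement holds for every fixed beta, hence also
    averaged over the prior).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (math.isfinite(g) and g > 0):
        raise ValueError(f"g must be positive, got {g}")
    se = np.resize(np.atleast_1d(np.asarray(se_values, dtype=float)), n)
    if np.any(se <= 0):
        raise ValueError("all se values must be positive")
    rng = np.random.default_rng(seed)
    beta = rng.standard_normal(n) * math.sqrt(g) * se
    b = beta + rng.standard_normal(n) * se
    return EstimateDraws(beta=beta, b=b, se=se)
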