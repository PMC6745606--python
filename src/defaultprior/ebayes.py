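"""Empirical-Bayes estimation of the prior variance ratio ``g`` from
collections of published z-values.

The hierarchical model.  Article ``j`` carries a latent variance ratio
``g_j ~ N(g, sigma^2)``; coefficient ``i`` of article ``j`` has
``beta_ij | g_j ~ N(0, g_j se_ij^2)`` and estimator
``B_ij | beta_ij ~ N(beta_ij, se_ij^2)``.  Consequently the z-value
``Z_ij = B_ij / se_ij`` is ``N(0, g_j + 1)`` given ``g_j``, and the squared
z-value is Gamma with shape 1/2 and mean ``g_j + 1`` (the ``chi^2_1``
scaling identity).  Fitting a Gamma mixed model with identity link, offset
one and a Gaussian study effect to the squared z-values therefore estimates
``g`` as the intercept.  A marginal (no-random-effect) Gamma model with
cluster-robust standard errors is provided as a cross-check.

The conditional likelihood integrates the Gaussian study effect by
Gauss-Hermite quadrature.  The identity link permits nonpositive Gamma means
in the Gaussian tail of the random effect; the integrand is treated as zero
there, which amounts to truncating the random-effect distribution to the
feasible region.  The truncated prior mass at the fitted parameters is
reported as a diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import chi2, norm

__all__ = [
    "ZDataset",
    "HierParams",
    "HierFit",
    "negloglik_conditional",
    "fit_conditional",
    "fit_marginal",
    "profile_ci_g",
    "truncated_mass",
]

_MEAN_FLOOR = 1e-10  # Gamma means at or below this are infeasible
_HALF_LOG_PI = 0.5 * math.log(math.pi)


@dataclass(frozen=True)
class ZDataset:
    """Squared z-values grouped by study (article).

    ``study_ids`` and ``z2`` are parallel arrays; records of a study need not
    be contiguous.
    """

    study_ids: np.ndarray
    z2: np.ndarray

    def __post_init__(self) -> None:
        sid = np.asarray(self.study_ids)
        z2 = np.asarray(self.z2, dtype=float)
        if sid.shape != z2.shape or z2.ndim != 1:
            raise ValueError("study_ids and z2 must be parallel 1-d arrays")
        if z2.size == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(z2)) or np.any(z2 < 0):
            raise ValueError("squared z-values must be finite and nonnegative")
        object.__setattr__(self, "study_ids", sid)
        object.__setattr__(self, "z2", z2)

    @classmethod
    def from_pairs(cls, pairs: "list[tuple[object, float]]") -> "ZDataset":
        sids, z2 = zip(*pairs)
        return cls(study_ids=np.asarray(sids), z2=np.asarray(z2, dtype=float))

    @property
    def n_values(self) -> int:
        return int(self.z2.size)

    @property
    def n_studies(self) -> int:
        return int(np.unique(self.study_ids).size)

    def sufficient_stats(self) -> "tuple[np.ndarray, np.ndarray, float]":
        """Per-study counts and sums of z^2, plus the total sum of log z^2.

        The Gamma shape-1/2 log-likelihood of a study depends on the data
        only through (n_j, sum_j z^2) and an additive constant in
        sum log z^2, so these are all the fit needs.
        """
        _, inv = np.unique(self.study_ids, return_inverse=True)
        n_j = np.bincount(inv).astype(float)
        s_j = np.bincount(inv, weights=self.z2)
        if np.any(self.z2 <= 0):
            raise ValueError(
                "squared z-values must be strictly positive for the Gamma "
                "likelihood (a z of exactly 0 has infinite density)"
            )
        logsum = float(np.sum(np.log(self.z2)))
        return n_j, s_j, logsum


@dataclass(frozen=True)
class HierParams:
    """Population parameters of the hierarchical model.

    ``g`` is the mean of the study-level variance ratios ``g_j`` (so the
    marginal mean of ``z^2`` is ``g + 1``); ``sigma`` is their standard
    deviation.  ``g + 1 > 0`` is required for a valid marginal mean.
    """

    g: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.g) or self.g + 1.0 <= 0:
            raise ValueError(f"g must be finite with g + 1 > 0, got {self.g}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")


@dataclass(frozen=True)
class HierFit:
    """Result of fitting the hierarchical (or marginal) Gamma model."""

    params: HierParams
    ci_g: "tuple[float, float]"
    loglik: float
    n_quad: int
    converged: bool
    method: str  # "conditional" or "marginal"
    ci_method: str = "profile"
    ci_flag: str = ""  # nonempty when the CI is one-sided or unavailable
    truncated_mass: float = 0.0
    message: str = ""
    n_studies: int = 0
    n_values: int = 0
    extra: dict = field(default_factory=dict)


def _study_loglik_at_means(
    means: np.ndarray, n_j: float, s_j: float
) -> np.ndarray:
    """Gamma(shape 1/2, mean m) log-likelihood of one study at each mean.

    ``log f(x; 1/2, m) = -0.5 log(2m) - 0.5 log(pi) - 0.5 log x - x/(2m)``;
    summed over the study's values only (n_j, s_j) enter, the ``log x`` term
    being a data-only constant handled by the caller.  Infeasible means give
    -inf.
    """
    means = np.asarray(means, dtype=float)
    out = np.full(means.shape, -np.inf)
    ok = means > _MEAN_FLOOR
    m = means[ok]
    out[ok] = -0.5 * n_j * (np.log(2.0 * m) + math.log(math.pi)) - s_j / (2.0 * m)
    return out


def _log_integrand_t(
    t: np.ndarray, g: float, sig: float, n_j: np.ndarray, s_j: np.ndarray
) -> np.ndarray:
    """Log of each study's random-effect integrand in ``t = log(mean)``.

    Substituting ``m = g + sigma*u + 1 = e^t`` maps the feasible region
    ``m > 0`` onto the whole real line and removes the essential singularity
    of the Gamma likelihood at ``m -> 0+``, so Gauss-Hermite quadrature in
    ``t`` converges spectrally.  Includes the Jacobian ``du = e^t/sigma dt``
    and the standard-normal density of ``u = (e^t - g - 1)/sigma``.
    """
    et = np.exp(t)
    u = (et - (g + 1.0)) / sig
    return (
        -0.5 * n_j * (math.log(2.0) + t + math.log(math.pi))
        - 0.5 * s_j * np.exp(-t)
        - 0.5 * np.square(u)
        - 0.5 * math.log(2.0 * math.pi)
        + t
        - math.log(sig)
    )


def _study_modes_t(
    g: float, sig: float, n_j: np.ndarray, s_j: np.ndarray
) -> "tuple[np.ndarray, np.ndarray]":
    """Mode and Laplace scale of each study's log integrand in t = log(mean).

    Closed-form first and second derivatives drive a vectorized Newton
    iteration; the scale is ``(-H'')^{-1/2}`` at the mode.
    """
    a = g + 1.0
    t = np.full_like(n_j, math.log(max(a, 1e-4)))
    h2 = np.full_like(n_j, -1.0)
    for _ in range(100):
        et = np.exp(t)
        u = (et - a) / sig
        h1 = -0.5 * n_j + 0.5 * s_j * np.exp(-t) - u * et / sig + 1.0
        h2 = -0.5 * s_j * np.exp(-t) - np.square(et / sig) - u * et / sig
        h2 = np.minimum(h2, -1e-8)  # keep the step a maximization step
        t_new = np.clip(t - h1 / h2, t - 2.0, t + 2.0)  # damp early oversteps
        if np.max(np.abs(t_new - t)) < 1e-13:
            t = t_new
            break
        t = t_new
    scale = 1.0 / np.sqrt(-h2)
    return t, scale


#: log-drop from the integrand peak that delimits the quadrature window;
#: mass beyond it is below exp(-45) of the peak, far under the tolerance.
_WINDOW_DROP = 45.0
#: convergence tolerance of the grid-doubling refinement, per call.
_QUAD_ATOL = 1e-9
_QUAD_MAX_NODES = 4096


def negloglik_conditional(
    params: HierParams, data: ZDataset, n_quad: int = 40
) -> float:
    """Negative log-likelihood of the conditional (mixed) Gamma model.

    For each study the Gaussian study effect ``u ~ N(0,1)`` is integrated
    out adaptively:

    .. math:: \\int \\prod_i \\mathrm{Gamma}\\big(z^2_{ij};\\,
              \\tfrac12,\\, g + \\sigma u + 1\\big)\\,\\phi(u)\\,du,

    restricted to the feasible region where the Gamma mean
    ``g + sigma*u + 1`` is positive (truncation of the random effect; the
    integrand vanishes there anyway).  The quadrature runs in
    ``t = log(mean)``, where the integrand is analytic with
    doubly-exponential tails, so the trapezoid rule on the effective
    support converges spectrally.  Starting from ``n_quad`` nodes the grid
    is doubled until the total log-likelihood changes by less than 1e-9, so
    the returned value is insensitive to the choice of ``n_quad``.  At
    ``sigma = 0`` the integral collapses exactly to the marginal model's
    log-likelihood.
    """
    if n_quad < 5:
        raise ValueError(f"n_quad must be >= 5, got {n_quad}")
    g, sig = params.g, params.sigma
    n_j, s_j, logsum = data.sufficient_stats()
    const = -0.5 * logsum  # the -0.5 * sum log z^2 term, data-only

    # a vanishing random effect collapses the integral to the marginal model;
    # below ~1e-8 relative sd the quadrature window would underflow anyway
    if sig <= 1e-8 * (abs(g) + 1.0):
        ll = float(np.sum(_study_loglik_at_means(np.array([g + 1.0]), n_j.sum(), s_j.sum())))
        if not np.isfinite(ll):
            raise ValueError("g + 1 <= 0 with sigma = 0: no valid Gamma mean")
        return -(ll + const)

    t_hat, scale = _study_modes_t(g, sig, n_j, s_j)
    peak = _log_integrand_t(t_hat, g, sig, n_j, s_j)

    # expand the window from the mode until the log integrand has dropped by
    # _WINDOW_DROP on each side
    lo = t_hat.copy()
    hi = t_hat.copy()
    for _ in range(400):
        need = _log_integrand_t(lo, g, sig, n_j, s_j) > peak - _WINDOW_DROP
        if not need.any():
            break
        lo = np.where(need, lo - 0.5 * scale, lo)
    for _ in range(400):
        need = _log_integrand_t(hi, g, sig, n_j, s_j) > peak - _WINDOW_DROP
        if not need.any():
            break
        hi = np.where(need, hi + 0.5 * scale, hi)

    def trapezoid_ll(n: int) -> np.ndarray:
        ts = lo[:, None] + (hi - lo)[:, None] * np.linspace(0.0, 1.0, n)[None, :]
        li = _log_integrand_t(ts, g, sig, n_j[:, None], s_j[:, None])
        li[:, 0] -= math.log(2.0)
        li[:, -1] -= math.log(2.0)
        return logsumexp(li, axis=1) + np.log((hi - lo) / (n - 1))

    n = n_quad
    ll_j = trapezoid_ll(n)
    while n < _QUAD_MAX_NODES:
        n = 2 * n
        ll_new = trapezoid_ll(n)
        done = abs(float(np.sum(ll_new - ll_j))) < _QUAD_ATOL
        ll_j = ll_new
        if done:
            break

    total = const + float(np.sum(ll_j))
    if not np.isfinite(total):
        raise ValueError("conditional likelihood is not finite at these parameters")
    return -total


def truncated_mass(params: HierParams) -> float:
    """Prior mass of the study-effect distribution in the infeasible region.

    The Gaussian ``g_j ~ N(g, sigma^2)`` puts mass on ``g_j + 1 <= 0``,
    where the Gamma mean would be nonpositive; the likelihood truncates it
    away.  Small for the parameter ranges of interest (about 1e-6 at
    ``g = 1.3, sigma = 0.5``) but reported as a diagnostic.
    """
    if params.sigma == 0.0:
        return 0.0
    return float(norm.cdf((-1.0 - params.g) / params.sigma))


def _optimize_nll(
    data: ZDataset, start: HierParams, n_quad: int
) -> "tuple[optimize.OptimizeResult, float]":
    def nll(theta: np.ndarray) -> float:
        g, sig = float(theta[0]), float(theta[1])
        try:
            return negloglik_conditional(HierParams(g=g, sigma=sig), data, n_quad)
        except ValueError:
            return np.inf

    res = optimize.minimize(
        nll,
        x0=np.array([start.g, start.sigma]),
        method="Nelder-Mead",
        bounds=[(-0.999, None), (0.0, None)],
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    return res, float(res.fun)


def fit_conditional(
    data: ZDataset,
    start: HierParams | None = None,
    n_quad: int = 40,
    ci_level: float = 0.95,
    ci_method: str = "profile",
) -> HierFit:
    """Maximum-likelihood fit of the conditional Gamma mixed model.

    Maximizes the Gauss-Hermite-integrated likelihood over ``(g, sigma)``
    with a Nelder-Mead search from the moment start
    ``(mean(z^2) - 1, 0.5)`` plus perturbed restarts, then attaches a
    confidence interval for ``g`` (profile likelihood by default, Wald via
    ``ci_method="wald"``).  Non-convergence is reported in the returned fit
    (``converged=False``), not raised.
    """
    if data.n_studies < 2:
        raise ValueError("the mixed fit needs at least 2 studies")
    if ci_method not in ("profile", "wald"):
        raise ValueError(f"ci_method must be 'profile' or 'wald', got {ci_method}")
    g0 = float(np.mean(data.z2)) - 1.0
    if start is None:
        start = HierParams(g=max(g0, -0.9), sigma=0.5)

    starts = [start]
    for dg, ds in ((0.5, 0.25), (-0.3, 1.0), (0.0, 0.05)):
        g_s = max(start.g + dg, -0.9)
        starts.append(HierParams(g=g_s, sigma=max(start.sigma + ds, 0.0)))

    best: optimize.OptimizeResult | None = None
    best_nll = np.inf
    for s in starts:
        res, val = _optimize_nll(data, s, n_quad)
        if val < best_nll:
            best, best_nll = res, val

    assert best is not None
    g_hat, sig_hat = float(best.x[0]), float(best.x[1])
    params = HierParams(g=g_hat, sigma=max(sig_hat, 0.0))
    converged = bool(best.success and np.isfinite(best_nll))
    fit = HierFit(
        params=params,
        ci_g=(math.nan, math.nan),
        loglik=-best_nll,
        n_quad=n_quad,
        converged=converged,
        method="conditional",
        ci_method=ci_method,
        truncated_mass=truncated_mass(params),
        message=str(best.message),
        n_studies=data.n_studies,
        n_values=data.n_values,
    )
    if not converged:
        return fit
    if ci_method == "profile":
        ci, flag = profile_ci_g(data, fit, level=ci_level)
    else:
        ci, flag = _wald_ci_g(data, fit, level=ci_level)
    return replace(fit, ci_g=ci, ci_flag=flag)


def _wald_ci_g(
    data: ZDataset, fit: HierFit, level: float
) -> "tuple[tuple[float, float], str]":
    """Wald interval from a central-difference Hessian of the log-likelihood."""
    g, sig = fit.params.g, fit.params.sigma
    h = max(1e-4, 1e-4 * abs(g))

    def nll_g(gv: float) -> float:
        return negloglik_conditional(HierParams(g=gv, sigma=sig), data, fit.n_quad)

    d2 = (nll_g(g + h) - 2.0 * nll_g(g) + nll_g(g - h)) / h**2
    if d2 <= 0:
        return (math.nan, math.nan), "hessian-not-positive"
    se_g = 1.0 / math.sqrt(d2)
    z = float(norm.ppf(0.5 * (1.0 + level)))
    return (g - z * se_g, g + z * se_g), ""


def fit_marginal(data: ZDataset, ci_level: float = 0.95) -> HierFit:
    """Fit the marginal (no-random-effect) Gamma model.

    An intercept-only Gamma regression with identity link, shape 1/2 and
    offset one: the maximum-likelihood intercept is ``mean(z^2) - 1``.  The
    fit is delegated to a ``statsmodels`` GLM with cluster-robust (by study)
    sandwich standard errors for the Wald CI; with fewer than 2 studies the
    CI is unavailable and flagged.
    """
    import statsmodels.api as sm

    n = data.n_values
    _, groups = np.unique(data.study_ids, return_inverse=True)
    if float(np.var(data.z2)) == 0.0:
        # degenerate constant data: the MLE is mean - 1 with no spread to
        # estimate a standard error from
        g_hat = float(np.mean(data.z2)) - 1.0
        params = HierParams(g=g_hat, sigma=0.0)
        return HierFit(
            params=params,
            ci_g=(g_hat, g_hat),
            loglik=-negloglik_conditional(params, data, n_quad=5),
            n_quad=0,
            converged=True,
            method="marginal",
            ci_method="degenerate",
            ci_flag="zero-variance-data",
            n_studies=data.n_studies,
            n_values=data.n_values,
        )
    with warnings.catch_warnings():
        # identity link is a deliberate (non-canonical) choice for this model
        warnings.simplefilter("ignore")
        model = sm.GLM(
            data.z2,
            np.ones((n, 1)),
            family=sm.families.Gamma(sm.families.links.Identity()),
            offset=np.ones(n),
        )
        start = np.array([float(np.mean(data.z2)) - 1.0])
        if data.n_studies >= 2:
            res = model.fit(
                start_params=start, cov_type="cluster", cov_kwds={"groups": groups}
            )
        else:
            res = model.fit(start_params=start)
    g_hat = float(res.params[0])
    params = HierParams(g=g_hat, sigma=0.0)
    ll = -negloglik_conditional(params, data, n_quad=5)
    if data.n_studies >= 2:
        z = float(norm.ppf(0.5 * (1.0 + ci_level)))
        se_g = float(res.bse[0])
        ci, flag = (g_hat - z * se_g, g_hat + z * se_g), ""
    else:
        ci, flag = (math.nan, math.nan), "robust-ci-needs->=2-studies"
    return HierFit(
        params=params,
        ci_g=ci,
        loglik=ll,
        n_quad=0,
        converged=bool(res.converged),
        method="marginal",
        ci_method="wald-cluster-robust",
        ci_flag=flag,
        n_studies=data.n_studies,
        n_values=data.n_values,
    )


def profile_ci_g(
    data: ZDataset, fit: HierFit, level: float = 0.95
) -> "tuple[tuple[float, float], str]":
    """Profile-likelihood confidence interval for ``g``.

    For fixed ``g`` the likelihood is maximized over ``sigma``; the interval
    endpoints are where twice the profile log-likelihood drop crosses the
    ``chi^2_1`` quantile, located by bracketing plus Brent root-finding to
    1e-4.  If the profile never crosses on one side within the search range
    the interval is one-sided and flagged.
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    g_hat, sig_hat = fit.params.g, fit.params.sigma
    ll_hat = fit.loglik
    crit = 0.5 * float(chi2.ppf(level, df=1))
    sig_hi = max(4.0 * sig_hat, 2.0)

    def profile_drop(g: float) -> float:
        """ll_hat - max_sigma ll(g, sigma) - crit; negative inside the CI."""
        def nll_s(sig: float) -> float:
            try:
                return negloglik_conditional(HierParams(g=g, sigma=sig), data, fit.n_quad)
            except ValueError:
                return np.inf

        r = optimize.minimize_scalar(nll_s, bounds=(0.0, sig_hi), method="bounded")
        return (ll_hat + float(r.fun)) - crit

    flag = ""
    step = max(0.25 * abs(g_hat) + 0.25, 0.25)

    def find_endpoint(direction: int) -> float:
        g_in = g_hat
        g_out = g_hat
        for _ in range(60):
            g_out = g_out + direction * step
            if g_out <= -0.999:
                g_out = -0.999 + 1e-6
                if profile_drop(g_out) < 0:
                    return math.nan  # never crosses before the boundary
                break
            if profile_drop(g_out) > 0:
                break
            g_in = g_out
        else:
            return math.nan
        lo, hi = (g_in, g_out) if direction > 0 else (g_out, g_in)
        return float(optimize.brentq(profile_drop, lo, hi, xtol=1e-4))

    low = find_endpoint(-1)
    high = find_endpoint(+1)
    if math.isnan(low):
        flag = "one-sided:lower-at-boundary"
    if math.isnan(high):
        flag = (flag + ";" if flag else "") + "one-sided:no-upper-crossing"
    return (low, high), flag
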