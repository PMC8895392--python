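"""Non-MCMC interval estimators for Poisson counts.

Four approaches that the Bayesian random-effects fits are benchmarked
against:

* exact (Garwood) Poisson confidence intervals from chi-square/gamma tail
  quantiles — guaranteed conservative;
* Byar's closed-form cubic approximation to the exact interval;
* empirical Bayes gamma-Poisson shrinkage: a gamma prior for the relative
  risks is estimated from the marginal negative-binomial likelihood, then
  each area gets its conjugate gamma posterior;
* a Poisson log-link random-intercept GLMM estimated by maximum likelihood
  via the Laplace approximation.

All intervals are returned on the case-count scale (the scale the
simulation study compares widths on); divide by E_i for rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .data import CountTable, IntervalEstimate, ValidationError


# ---------------------------------------------------------------------------
# exact and Byar intervals
# ---------------------------------------------------------------------------

def exact_poisson_interval(x, level: float = 0.95):
    """Garwood exact confidence interval for a Poisson mean.

    lower = chi2.ppf(alpha/2, 2x)/2 (zero when x = 0) and
    upper = chi2.ppf(1 - alpha/2, 2x + 2)/2, equivalently gamma quantiles
    with shapes x and x + 1.  Vectorised over ``x``.
    """
    x = np.asarray(x)
    _check_counts(x, level)
    alpha = 1.0 - level
    xf = x.astype(float)
    lower = np.where(xf > 0, stats.gamma.ppf(alpha / 2, np.maximum(xf, 1)), 0.0)
    upper = stats.gamma.ppf(1 - alpha / 2, xf + 1)
    if x.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def byars_interval(x, level: float = 0.95):
    """Byar's cubic approximation to the exact Poisson interval.

    lower = x (1 - 1/(9x) - z/(3 sqrt(x)))^3 for x >= 1 (0 at x = 0);
    upper = (x+1) (1 - 1/(9(x+1)) + z/(3 sqrt(x+1)))^3.
    """
    x = np.asarray(x)
    _check_counts(x, level)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    xf = x.astype(float)
    xs = np.maximum(xf, 1.0)
    lower = np.where(
        xf > 0, xs * (1 - 1 / (9 * xs) - z / (3 * np.sqrt(xs))) ** 3, 0.0)
    xp = xf + 1.0
    upper = xp * (1 - 1 / (9 * xp) + z / (3 * np.sqrt(xp))) ** 3
    if x.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def _check_counts(x, level):
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0,1), got {level}")
    if np.any(np.asarray(x) < 0):
        raise ValidationError("counts must be non-negative")


# ---------------------------------------------------------------------------
# empirical Bayes gamma-Poisson
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EbGammaFit:
    """Estimated gamma prior R_i ~ Gamma(alpha, rate=beta) and its marginal
    negative-binomial log-likelihood; ``boundary`` flags an optimum pinned at
    the homogeneous (alpha -> large) edge of the search box."""

    alpha: float
    beta: float
    loglik: float
    boundary: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and self.alpha > 0
                and np.isfinite(self.beta) and self.beta > 0):
            raise ValidationError("alpha and beta must be finite and positive")


_EB_LOG_BOUNDS = (-12.0, 14.0)


def _nb_negloglik(logab: np.ndarray, C: np.ndarray, E: np.ndarray) -> float:
    a, b = np.exp(logab)
    # marginal of C_i with R_i ~ Gamma(a, rate b): NegBin(size=a, p=b/(b+E))
    p = b / (b + E)
    ll = np.sum(gammaln(C + a) - gammaln(a) - gammaln(C + 1)
                + a * np.log(p) + C * np.log1p(-p))
    return -float(ll)


def fit_eb_gamma(table: CountTable, method: str = "ml") -> EbGammaFit:
    """Estimate the gamma relative-risk prior from the marginal likelihood.

    ``method='ml'`` maximises the negative-binomial marginal likelihood on
    (log alpha, log beta) by bounded quasi-Newton from method-of-moments
    start values; ``method='moments'`` returns the moment estimates
    directly.
    """
    C = table.observed.astype(float)
    E = table.expected
    if C.sum() < 1:
        raise ValidationError(
            "all counts are zero: the marginal likelihood is maximised at a "
            "degenerate boundary and carries no information about the prior"
        )
    # method-of-moments start: R ~ Gamma(a, b), E[R]=a/b, Var[R]=a/b^2
    ratio = C / E
    rbar = C.sum() / E.sum()
    between = max(np.var(ratio, ddof=1) - rbar * np.mean(1.0 / E), 1e-6)
    a0 = max(rbar ** 2 / between, 1e-4)
    b0 = max(rbar / between, 1e-4)
    if method == "moments":
        return EbGammaFit(alpha=a0, beta=b0,
                          loglik=-_nb_negloglik(np.log([a0, b0]), C, E))
    if method != "ml":
        raise ValidationError(f"unknown EB method {method!r}")
    x0 = np.clip(np.log([a0, b0]), *_EB_LOG_BOUNDS)
    res = optimize.minimize(
        _nb_negloglik, x0, args=(C, E), method="L-BFGS-B",
        bounds=[_EB_LOG_BOUNDS] * 2,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    a, b = np.exp(res.x)
    # flat marginal likelihoods stall the optimizer near (not at) the box
    # edge, so "boundary" means within half a log-unit of it
    boundary = bool(np.any(np.abs(res.x - np.array(_EB_LOG_BOUNDS)[None, :])
                           < 0.5))
    return EbGammaFit(alpha=float(a), beta=float(b), loglik=-float(res.fun),
                      boundary=boundary)


def eb_interval(fit: EbGammaFit, x: int, e: float, level: float = 0.95,
                area_id: str = "", method: str = "eb") -> IntervalEstimate:
    """Conjugate gamma posterior interval for lambda = R e.

    Posterior for R is Gamma(alpha + x, rate beta + e); the lambda interval
    multiplies the equal-tail gamma quantiles by e, and the point estimate is
    the posterior mean e (alpha + x) / (beta + e).
    """
    if x < 0 or e <= 0:
        raise ValidationError("need x >= 0 and e > 0")
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0,1), got {level}")
    alpha_tail = (1 - level) / 2
    shape = fit.alpha + x
    rate = fit.beta + e
    lower = e * stats.gamma.ppf(alpha_tail, shape, scale=1.0 / rate)
    upper = e * stats.gamma.ppf(1 - alpha_tail, shape, scale=1.0 / rate)
    point = e * shape / rate
    return IntervalEstimate(method=method, area_id=area_id,
                            point=float(point), lower=float(lower),
                            upper=float(upper), level=level)


def eb_intervals(table: CountTable, level: float = 0.95,
                 fit: EbGammaFit | None = None) -> list[IntervalEstimate]:
    fit = fit if fit is not None else fit_eb_gamma(table)
    return [
        eb_interval(fit, int(table.observed[i]), float(table.expected[i]),
                    level, area_id=a)
        for i, a in enumerate(table.area_ids)
    ]


# ---------------------------------------------------------------------------
# maximum-likelihood GLMM (Laplace)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmmFit:
    mu_hat: float
    sigma_hat: float
    nu_modes: np.ndarray
    nu_sd: np.ndarray
    converged: bool
    loglik: float = float("nan")


_GLMM_LOGSIG_BOUNDS = (-8.0, 3.0)


def _glmm_modes(mu: float, sigma2: float, C: np.ndarray, E: np.ndarray,
                tol: float = 1e-10, max_iter: int = 100):
    """Conditional modes of the random intercepts by per-area Newton steps.

    Each area contributes g(nu) = C nu - E exp(mu + nu) - nu^2/(2 sigma^2)
    (up to constants); areas are independent so the Newton iteration is
    vectorised.  Returns (modes, curvature h = -g'').
    """
    nu = np.zeros_like(E)
    for _ in range(max_iter):
        lam = E * np.exp(mu + nu)
        grad = C - lam - nu / sigma2
        hess = lam + 1.0 / sigma2
        step = grad / hess
        step = np.clip(step, -2.0, 2.0)  # damping for tiny-count areas
        nu = nu + step
        if np.max(np.abs(step)) < tol:
            break
    lam = E * np.exp(mu + nu)
    return nu, lam + 1.0 / sigma2


def _glmm_negloglik(params: np.ndarray, C: np.ndarray, E: np.ndarray) -> float:
    mu, logsig = params
    sigma2 = np.exp(2 * logsig)
    nu, h = _glmm_modes(mu, sigma2, C, E)
    g = (C * (mu + nu + np.log(E)) - E * np.exp(mu + nu) - gammaln(C + 1)
         - 0.5 * nu ** 2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2))
    ll = np.sum(g + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(h))
    return -float(ll)


def fit_glmm_ml(table: CountTable) -> GlmmFit:
    """ML fit of the Poisson random-intercept model via Laplace approximation.

    The marginal likelihood is maximised over (mu, log sigma); a sigma
    estimate pinned at the lower search bound is reported as (effectively)
    zero heterogeneity.  Non-convergence is flagged, not raised.
    """
    C = table.observed.astype(float)
    E = table.expected
    mu0 = np.log((C.sum() + 0.5) / E.sum())
    res = optimize.minimize(
        _glmm_negloglik, np.array([mu0, np.log(0.5)]), args=(C, E),
        method="L-BFGS-B",
        bounds=[(-30.0, 30.0), _GLMM_LOGSIG_BOUNDS],
        options={"maxiter": 500},
    )
    mu_hat, logsig = res.x
    sigma_hat = float(np.exp(logsig))
    if logsig <= _GLMM_LOGSIG_BOUNDS[0] + 1e-6:
        sigma_hat = 0.0
    nu, h = _glmm_modes(mu_hat, max(sigma_hat, 1e-8) ** 2, C, E)
    return GlmmFit(mu_hat=float(mu_hat), sigma_hat=sigma_hat,
                   nu_modes=nu, nu_sd=1.0 / np.sqrt(h),
                   converged=bool(res.success), loglik=-float(res.fun))


def glmm_intervals(fit: GlmmFit, table: CountTable,
                   level: float = 0.95) -> list[IntervalEstimate]:
    """Per-area lambda intervals exp(mu + nu_i +/- z sd_i) E_i from the
    conditional curvature at the modes (hyperparameter uncertainty in
    (mu, sigma) is not propagated)."""
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0,1), got {level}")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    eta = fit.mu_hat + fit.nu_modes
    point = np.exp(eta) * table.expected
    lower = np.exp(eta - z * fit.nu_sd) * table.expected
    upper = np.exp(eta + z * fit.nu_sd) * table.expected
    return [
        IntervalEstimate(method="glmm", area_id=a, point=float(point[i]),
                         lower=float(lower[i]), upper=float(upper[i]),
                         level=level)
        for i, a in enumerate(table.area_ids)
    ]
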