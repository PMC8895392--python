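"""Bayesian model-fit criteria from posterior draws: deviance, pD, DIC, WAIC.

Conventions fixed here (they only matter up to additive constants shared by
all models, but are fixed for determinism):

* the Poisson deviance includes the ``log C_i!`` normalising term, i.e.
  ``-2 log p(C | lambda)`` in full;
* the DIC plug-in deviance is evaluated at the per-area posterior-mean
  lambda;
* the two WAIC effective-parameter penalties are the Jensen gap
  ``p1 = 2 sum_i (lppd_i - mean_s log p_i,s)`` and the per-area sample
  variance of the log predictive density over draws (``S - 1`` denominator),
  with ``WAIC_k = -2 (lppd - p_k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import CountTable, ValidationError
from .mcmc import PosteriorFit


@dataclass(frozen=True)
class CriteriaResult:
    dbar: float | None = None
    d_at_mean: float | None = None
    pd: float | None = None
    dic: float | None = None
    lppd: float | None = None
    p_waic1: float | None = None
    p_waic2: float | None = None
    waic1: float | None = None
    waic2: float | None = None

    def merged(self, other: "CriteriaResult") -> "CriteriaResult":
        kwargs = {}
        for k in self.__dataclass_fields__:
            a, b = getattr(self, k), getattr(other, k)
            kwargs[k] = b if a is None else a
        return CriteriaResult(**kwargs)


def _logpmf(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Poisson log-pmf, broadcasting counts against lambda draws."""
    counts = np.asarray(counts, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return counts * np.log(lam) - lam - gammaln(counts + 1)


def poisson_deviance(table: CountTable, lam) -> float:
    """-2 sum_i log PoissonPmf(C_i; lambda_i), log C_i! term included."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValidationError("lambda values must be positive and finite")
    return -2.0 * float(np.sum(_logpmf(table.observed, lam)))


def compute_dic(fit: PosteriorFit, min_draws: int = 100) -> CriteriaResult:
    """Mean deviance, plug-in deviance at the posterior-mean lambda, and the
    identities pD = dbar - d_at_mean, DIC = dbar + pD."""
    _require_draws(fit, min_draws)
    logp = _logpmf(fit.data.observed[None, :], fit.draws_lambda)  # (S, I)
    dbar = float(np.mean(-2.0 * logp.sum(axis=1)))
    d_at_mean = poisson_deviance(fit.data, fit.draws_lambda.mean(axis=0))
    pd = dbar - d_at_mean
    return CriteriaResult(dbar=dbar, d_at_mean=d_at_mean, pd=pd,
                          dic=dbar + pd)


def compute_waic(fit: PosteriorFit, min_draws: int = 100) -> CriteriaResult:
    """Both WAIC variants from the pointwise log predictive density."""
    _require_draws(fit, min_draws)
    S = fit.n_draws
    if S < 2:
        raise ValidationError("WAIC variance penalty needs at least 2 draws")
    logp = _logpmf(fit.data.observed[None, :], fit.draws_lambda)  # (S, I)
    lppd_i = logsumexp(logp, axis=0) - np.log(S)
    mean_logp = logp.mean(axis=0)
    p1_i = 2.0 * (lppd_i - mean_logp)
    p2_i = logp.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p1 = float(p1_i.sum())
    p2 = float(p2_i.sum())
    return CriteriaResult(lppd=lppd, p_waic1=p1, p_waic2=p2,
                          waic1=-2.0 * (lppd - p1), waic2=-2.0 * (lppd - p2))


def evaluate_fit(fit: PosteriorFit, min_draws: int = 100) -> CriteriaResult:
    """All criteria for one fit (DIC and WAIC families together)."""
    return compute_dic(fit, min_draws).merged(compute_waic(fit, min_draws))


def _require_draws(fit: PosteriorFit, n: int) -> None:
    if fit.n_draws < n:
        raise ValidationError(f"at least {n} kept draws required, "
                              f"got {fit.n_draws}")
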