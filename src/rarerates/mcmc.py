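"""Metropolis-within-Gibbs sampler for the Poisson random-effects model.

Model
-----
Counts per area follow ``C_i ~ Poisson(R_i E_i)`` with log relative risk
``log R_i = mu + nu_i`` and exchangeable random intercepts
``nu_i ~ Normal(0, sigma^2)``.  The intercept ``mu`` carries a flat improper
prior; the random-effect scale ``sigma`` carries one of the priors in
:class:`rarerates.data.PriorSpec` (bounded uniforms with varying lower
bounds, a hierarchical uniform whose bounds are themselves sampled, or a
gamma prior on the precision ``tau = 1/sigma^2``).

Sampler
-------
Single-site random-walk Metropolis on ``mu`` and (vectorised, since they are
conditionally independent) on each ``nu_i``; ``sigma`` is updated by a
bounded random walk under uniform priors or an exact conjugate Gibbs draw of
``tau ~ Gamma(shape + I/2, rate + sum(nu^2)/2)`` under the gamma prior.  Every
iteration additionally applies an interweaved non-centred step: with
``z = nu/sigma`` held fixed, ``log sigma`` is moved by Metropolis and ``nu``
rescaled on acceptance.  The centred/non-centred interweaving keeps mixing
acceptable both for large counts (where the centred parameterisation is
efficient) and for near-zero counts under heavy-shrinkage priors (where the
posterior of ``(sigma, nu)`` is funnel-shaped).  Proposal scales adapt toward
a 30-45% acceptance rate during burn-in and are frozen afterwards.

The sampler runs many chains/replicates as rows of a batch, which is what
makes the simulation studies tractable: every update is an elementwise
operation on ``(batch, I)`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .data import (CountTable, IntervalEstimate, McmcConfig, PriorSpec,
                   ValidationError, spawn_seeds)

_ACCEPT_TARGET = 0.37  # midpoint of the 30-45% band aimed for during burn-in
_ADAPT_WINDOW = 50


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def poisson_loglik(counts, expected, mu, nu) -> float:
    """Poisson log-likelihood sum_i [C_i log(lambda_i) - lambda_i - log C_i!]
    with lambda_i = exp(mu + nu_i) E_i."""
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected, dtype=float)
    nu = np.asarray(nu, dtype=float)
    loglam = mu + nu + np.log(expected)
    return float(np.sum(counts * loglam - np.exp(loglam) - gammaln(counts + 1)))


def _sigma_log_prior(sigma, prior: PriorSpec, lb=None, ub=None):
    """Log prior density of sigma (vectorised; -inf outside support).

    For the gamma-precision family the density of tau is transformed to the
    sigma scale (Jacobian 2/sigma^3).  For uniform families ``lb``/``ub``
    override the PriorSpec bounds (used by the hierarchical model where the
    bounds are state).
    """
    sigma = np.asarray(sigma, dtype=float)
    out = np.full(sigma.shape, -np.inf)
    pos = sigma > 0
    if prior.family == "gamma_precision":
        a, b = prior.gamma_shape, prior.gamma_rate
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = sigma ** -2.0
            val = (a * np.log(b) - gammaln(a) + (a - 1) * np.log(tau)
                   - b * tau + np.log(2.0) - 3.0 * np.log(sigma))
        out[pos] = val[pos]
        return out
    lo = prior.lb if lb is None else np.asarray(lb, dtype=float)
    hi = prior.ub if ub is None else np.asarray(ub, dtype=float)
    inside = pos & (sigma >= lo) & (sigma <= hi)
    val = np.broadcast_to(np.asarray(-np.log(hi - lo), dtype=float), sigma.shape)
    out[inside] = val[inside]
    return out


def log_joint(table: CountTable, mu: float, nu, sigma: float,
              prior: PriorSpec, lb: float | None = None,
              ub: float | None = None) -> float:
    """Unnormalised log posterior density of ``(mu, nu, sigma)``.

    Returns -inf for states outside the prior support.  For the hierarchical
    family the density is conditional on the current bounds ``(lb, ub)``.
    """
    nu = np.asarray(nu, dtype=float)
    if sigma <= 0:
        return -np.inf
    lp_sigma = float(_sigma_log_prior(np.array([sigma]), prior, lb=lb, ub=ub)[0])
    if not np.isfinite(lp_sigma):
        return -np.inf
    ll = poisson_loglik(table.observed, table.expected, mu, nu)
    lp_nu = float(-0.5 * np.sum(nu ** 2) / sigma ** 2
                  - nu.size * np.log(sigma)
                  - 0.5 * nu.size * np.log(2 * np.pi))
    return ll + lp_nu + lp_sigma


# ---------------------------------------------------------------------------
# batch sampler
# ---------------------------------------------------------------------------

def _sample_batch(counts: np.ndarray, expected: np.ndarray, prior: PriorSpec,
                  cfg: McmcConfig, seed: int) -> dict:
    """Run one chain per batch row; rows are independent datasets or chains.

    Returns kept draws as arrays: mu (B,S), sigma (B,S), nu (B,S,I) and, for
    the hierarchical prior, lb/ub (B,S).
    """
    C = np.asarray(counts, dtype=float)
    E = np.asarray(expected, dtype=float)
    B, I = C.shape
    rng = np.random.default_rng(seed)
    hier = prior.family == "hierarchical_uniform_sigma"
    gam = prior.family == "gamma_precision"

    # --- deterministic initialisation (inside support) -------------------
    sumC = C.sum(axis=1)
    sumE = E.sum(axis=1)
    mu = np.where(sumC > 0, np.log(np.maximum(sumC, 1e-300) / sumE), 0.0)
    nu = np.zeros((B, I))
    if gam:
        sig = np.full(B, 0.5)
    elif hier:
        lb_s = np.full(B, 0.0)
        ub_s = np.full(B, prior.ub_hyper_max / 2.0)
        sig = np.full(B, 0.5)
    else:
        mid = 0.5 * (prior.lb + prior.ub)
        sig = np.full(B, float(np.clip(mid, 0.01, 2.0)))
        sig = np.clip(sig, prior.lb + 1e-9 if prior.lb > 0 else 0.01, prior.ub)
    if not hier:
        lb_s = np.full(B, prior.lb)
        ub_s = np.full(B, prior.ub)

    enu = np.exp(nu)
    logsig = np.log(sig)

    # proposal scales: information-based starting points, adapted in burn-in
    s_mu = 2.4 / np.sqrt(sumC + 1.0)
    s_nu = 2.4 / np.sqrt(C + 1.0)
    s_sig = np.full(B, cfg.proposal_scales[2])
    s_nc = np.full(B, 0.3)
    s_lb = np.full(B, 0.5)
    s_ub = np.full(B, 20.0)

    a_mu = np.zeros(B)
    a_nu = np.zeros((B, I))
    a_sig = np.zeros(B)
    a_nc = np.zeros(B)
    a_lb = np.zeros(B)
    a_ub = np.zeros(B)

    n_keep = cfg.n_keep_per_chain
    out_mu = np.empty((B, n_keep))
    out_sig = np.empty((B, n_keep))
    out_nu = np.empty((B, n_keep, I))
    if hier:
        out_lb = np.empty((B, n_keep))
        out_ub = np.empty((B, n_keep))

    total = cfg.n_burnin + cfg.n_iter
    keep_idx = 0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for t in range(total):
            # ---- mu: scalar random walk per row -------------------------
            mu_p = mu + s_mu * rng.standard_normal(B)
            w = (E * enu).sum(axis=1)
            dll = (mu_p - mu) * sumC - (np.exp(mu_p) - np.exp(mu)) * w
            acc = np.log(rng.random(B)) < dll
            mu = np.where(acc, mu_p, mu)
            a_mu += acc

            # ---- nu: elementwise random walk (cond. independent) --------
            nu_p = nu + s_nu * rng.standard_normal((B, I))
            enu_p = np.exp(nu_p)
            emu = np.exp(mu)[:, None]
            inv2s2 = (0.5 / sig ** 2)[:, None]
            dll = (C * (nu_p - nu) - E * emu * (enu_p - enu)
                   - (nu_p ** 2 - nu ** 2) * inv2s2)
            acc = np.log(rng.random((B, I))) < dll
            nu = np.where(acc, nu_p, nu)
            enu = np.where(acc, enu_p, enu)
            a_nu += acc

            ss = (nu ** 2).sum(axis=1)

            # ---- sigma, centred parameterisation ------------------------
            if gam:
                tau = rng.gamma(prior.gamma_shape + 0.5 * I,
                                1.0 / (prior.gamma_rate + 0.5 * ss))
                sig = 1.0 / np.sqrt(tau)
                logsig = np.log(sig)
            else:
                sig_p = sig + s_sig * rng.standard_normal(B)
                ok = (sig_p >= lb_s) & (sig_p <= ub_s) & (sig_p > 0)
                dll = np.where(
                    ok,
                    -I * (np.log(np.where(ok, sig_p, 1.0)) - logsig)
                    - 0.5 * ss * (np.where(ok, sig_p, 1.0) ** -2 - sig ** -2),
                    -np.inf,
                )
                acc = np.log(rng.random(B)) < dll
                sig = np.where(acc, sig_p, sig)
                logsig = np.log(sig)
                a_sig += acc

            # ---- sigma, non-centred (interweaved) -----------------------
            z = nu / sig[:, None]
            logsig_p = logsig + s_nc * rng.standard_normal(B)
            sig_p = np.exp(logsig_p)
            nu_p = sig_p[:, None] * z
            enu_p = np.exp(nu_p)
            emu = np.exp(mu)
            pois_new = (C * nu_p).sum(axis=1) - (E * enu_p).sum(axis=1) * emu
            pois_old = (C * nu).sum(axis=1) - (E * enu).sum(axis=1) * emu
            lp_new = _sigma_log_prior(sig_p, prior, lb=lb_s, ub=ub_s)
            lp_old = _sigma_log_prior(sig, prior, lb=lb_s, ub=ub_s)
            dll = (pois_new - pois_old) + (lp_new - lp_old) + (logsig_p - logsig)
            acc = np.log(rng.random(B)) < dll
            sig = np.where(acc, sig_p, sig)
            logsig = np.where(acc, logsig_p, logsig)
            nu = np.where(acc[:, None], nu_p, nu)
            enu = np.where(acc[:, None], enu_p, enu)
            a_nc += acc

            # ---- hierarchical bounds ------------------------------------
            if hier:
                lb_p = lb_s + s_lb * rng.standard_normal(B)
                ok = ((lb_p >= 0) & (lb_p <= prior.lb_hyper_max)
                      & (lb_p <= sig))
                safe = np.where(ok, lb_p, 0.0)
                dll = np.where(
                    ok,
                    -np.log(prior.ub_hyper_max - safe)
                    + np.log(prior.ub_hyper_max - lb_s)
                    - np.log(ub_s - safe) + np.log(ub_s - lb_s),
                    -np.inf,
                )
                acc = np.log(rng.random(B)) < dll
                lb_s = np.where(acc, lb_p, lb_s)
                a_lb += acc

                ub_p = ub_s + s_ub * rng.standard_normal(B)
                ok = (ub_p <= prior.ub_hyper_max) & (ub_p >= sig) & (ub_p > lb_s)
                safe = np.where(ok, ub_p, lb_s + 1.0)
                dll = np.where(ok,
                               -np.log(safe - lb_s) + np.log(ub_s - lb_s),
                               -np.inf)
                acc = np.log(rng.random(B)) < dll
                ub_s = np.where(acc, ub_p, ub_s)
                a_ub += acc

            # ---- adaptation during burn-in ------------------------------
            if cfg.adapt and t < cfg.n_burnin and (t + 1) % _ADAPT_WINDOW == 0:
                def _tune(scale, hits):
                    rate = hits / _ADAPT_WINDOW
                    return np.clip(scale * np.exp(rate - _ACCEPT_TARGET),
                                   1e-6, 100.0)
                s_mu = _tune(s_mu, a_mu)
                s_nu = _tune(s_nu, a_nu)
                s_nc = _tune(s_nc, a_nc)
                if not gam:
                    s_sig = _tune(s_sig, a_sig)
                if hier:
                    s_lb = _tune(s_lb, a_lb)
                    s_ub = _tune(s_ub, a_ub)
                a_mu[:] = 0; a_nu[:] = 0; a_sig[:] = 0
                a_nc[:] = 0; a_lb[:] = 0; a_ub[:] = 0

            # ---- storage ------------------------------------------------
            if t >= cfg.n_burnin and (t - cfg.n_burnin) % cfg.thin == 0 \
                    and keep_idx < n_keep:
                out_mu[:, keep_idx] = mu
                out_sig[:, keep_idx] = sig
                out_nu[:, keep_idx] = nu
                if hier:
                    out_lb[:, keep_idx] = lb_s
                    out_ub[:, keep_idx] = ub_s
                keep_idx += 1

    out = {"mu": out_mu, "sigma": out_sig, "nu": out_nu}
    if hier:
        out["lb"] = out_lb
        out["ub"] = out_ub
    return out


# ---------------------------------------------------------------------------
# posterior container and public fitting API
# ---------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    """Kept MCMC draws for one count table under one prior.

    ``draws_lambda[s, i] == exp(draws_mu[s] + draws_nu[s, i]) * E_i`` by
    construction.
    """

    draws_mu: np.ndarray            # (S,)
    draws_sigma: np.ndarray         # (S,)
    draws_nu: np.ndarray            # (S, I)
    draws_lambda: np.ndarray        # (S, I)
    prior: PriorSpec
    data: CountTable
    diagnostics: dict
    n_chains: int = 1
    draws_lb: np.ndarray | None = None
    draws_ub: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.draws_mu.shape[0]


def fit_bayes(table: CountTable, prior: PriorSpec,
              mcmc: McmcConfig | None = None) -> PosteriorFit:
    """Fit the Poisson random-effects model by MCMC under ``prior``.

    Chains are run as batch rows with per-chain substreams of ``mcmc.seed``;
    kept draws from all chains are concatenated.  Split-R-hat and effective
    sample size are computed on ``mu`` and ``sigma``; R-hat above 1.1 sets a
    non-fatal warning flag in ``diagnostics``.
    """
    return fit_bayes_batch([table], prior, mcmc)[0]


def fit_bayes_batch(tables: Sequence[CountTable], prior: PriorSpec,
                    mcmc: McmcConfig | None = None) -> list[PosteriorFit]:
    """Fit several same-size count tables in one vectorised sampler run."""
    cfg = mcmc if mcmc is not None else McmcConfig()
    n_tab = len(tables)
    if n_tab == 0:
        raise ValidationError("no tables to fit")
    I = tables[0].n_areas
    if any(t.n_areas != I for t in tables):
        raise ValidationError("batch fitting requires equal area counts")

    # initial state must have finite log joint (it does by construction, but
    # pathological inputs such as overflowing expected counts are caught here)
    sig0 = 0.5 if prior.family != "uniform_sigma" else float(
        np.clip(0.5 * (prior.lb + prior.ub), max(0.01, prior.lb), 2.0 + prior.lb))
    for t in tables:
        mu0 = np.log(t.observed.sum() / t.expected.sum()) \
            if t.observed.sum() > 0 else 0.0
        if not np.isfinite(log_joint(t, mu0, np.zeros(I), sig0, prior,
                                     lb=0.0 if prior.family ==
                                     "hierarchical_uniform_sigma" else None,
                                     ub=prior.ub_hyper_max / 2 if prior.family ==
                                     "hierarchical_uniform_sigma" else None)):
            raise ValidationError(
                f"non-finite initial log-joint for entity {t.entity_id!r}"
            )

    C = np.repeat(np.stack([t.observed for t in tables]), cfg.n_chains, axis=0)
    E = np.repeat(np.stack([t.expected for t in tables]), cfg.n_chains, axis=0)
    draws = _sample_batch(C, E, prior, cfg, seed=spawn_seeds(cfg.seed, 1)[0])

    S = cfg.n_keep_per_chain
    fits = []
    for k, table in enumerate(tables):
        rows = slice(k * cfg.n_chains, (k + 1) * cfg.n_chains)
        mu_c = draws["mu"][rows]          # (chains, S)
        sig_c = draws["sigma"][rows]
        nu_c = draws["nu"][rows]          # (chains, S, I)
        diagnostics = {}
        rhat_mu, ess_mu = rhat_ess(mu_c)
        rhat_sig, ess_sig = rhat_ess(sig_c)
        diagnostics.update(rhat_mu=rhat_mu, ess_mu=ess_mu,
                           rhat_sigma=rhat_sig, ess_sigma=ess_sig)
        diagnostics["converged"] = bool(
            (np.isnan(rhat_mu) or rhat_mu < 1.1)
            and (np.isnan(rhat_sig) or rhat_sig < 1.1))
        mu_all = mu_c.reshape(-1)
        sig_all = sig_c.reshape(-1)
        nu_all = nu_c.reshape(-1, I)
        lam = np.exp(mu_all[:, None] + nu_all) * table.expected[None, :]
        fit = PosteriorFit(
            draws_mu=mu_all, draws_sigma=sig_all, draws_nu=nu_all,
            draws_lambda=lam, prior=prior, data=table,
            diagnostics=diagnostics, n_chains=cfg.n_chains,
            draws_lb=draws["lb"][rows].reshape(-1) if "lb" in draws else None,
            draws_ub=draws["ub"][rows].reshape(-1) if "ub" in draws else None,
        )
        fits.append(fit)
    return fits


def lambda_intervals(fit: PosteriorFit, level: float = 0.95
                     ) -> list[IntervalEstimate]:
    """Equal-tail credible intervals for the expected case counts lambda_i.

    Point estimate is the posterior mean (the expectation of the predicted
    number of cases); bounds are the (1-level)/2 and 1-(1-level)/2 empirical
    quantiles of the lambda draws (linear interpolation convention).
    """
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0,1), got {level}")
    if fit.n_draws < 100:
        raise ValidationError("at least 100 kept draws required")
    alpha = 1.0 - level
    lo = np.quantile(fit.draws_lambda, alpha / 2, axis=0)
    hi = np.quantile(fit.draws_lambda, 1 - alpha / 2, axis=0)
    pt = fit.draws_lambda.mean(axis=0)
    tag = f"bayes[{fit.prior.family}]"
    return [
        IntervalEstimate(method=tag, area_id=a, point=float(pt[i]),
                         lower=float(lo[i]), upper=float(hi[i]), level=level)
        for i, a in enumerate(fit.data.area_ids)
    ]


def posterior_sigma_mean(fit: PosteriorFit) -> float:
    return float(fit.draws_sigma.mean())


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def rhat_ess(chains) -> tuple[float, float]:
    """Split potential-scale-reduction R-hat and effective sample size.

    ``chains`` is an (m, n) array of m chains with n draws each.  Chains are
    split in half before computing between/within variances.  For a single
    chain R-hat is undefined (NaN) and only the ESS is returned.  Constant
    chains return R-hat 1 by convention.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if n < 10:
        raise ValidationError("at least 10 draws per chain required")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)

    ess = _ess(split)
    if m < 2:
        return float("nan"), ess

    means = split.mean(axis=1)
    vars_ = split.var(axis=1, ddof=1)
    W = vars_.mean()
    Bv = half * means.var(ddof=1)
    if W <= 0:
        return 1.0 if Bv <= 0 else float("inf"), ess
    var_plus = (half - 1) / half * W + Bv / half
    return float(np.sqrt(var_plus / W)), ess


def _ess(split: np.ndarray) -> float:
    """Effective sample size from combined split-chain autocorrelations
    (initial-positive-sequence truncation)."""
    m, n = split.shape
    means = split.mean(axis=1, keepdims=True)
    vars_ = split.var(axis=1, ddof=1)
    W = vars_.mean()
    Bv = n * split.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + Bv / n
    if var_plus <= 0:
        return float(m * n)
    centered = split - means
    # per-chain autocovariances via FFT
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=size, axis=1)[:, :n].real / n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    # Geyer initial positive sequence on paired sums
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
        t += 2
    return float(m * n / tau)
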