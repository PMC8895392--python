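"""Simulation benchmark: coverage, width and RMSE of 95% intervals.

For a generating scenario, J replicate datasets are drawn and every
requested estimation approach produces per-area intervals for the expected
case counts.  Three indicators are aggregated per method:

* coverage: percentage of the pooled I x J intervals containing the
  replicate's true lambda_i (closed-interval convention); the reported SD is
  that of the pooled binary indicators, so SD ~ 100 sqrt(p(1-p));
* width: mean and SD of the pooled I x J interval widths (case scale);
* RMSE: per replicate, the root of the mean squared error over areas
  between the point estimate and the true lambda; mean and SD taken over
  replicates (a per-interval aggregation is available via
  ``rmse_per_interval``).

Bayesian methods run through the vectorised batch sampler, chunked over
replicates to bound memory.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import classical
from .data import (IntervalEstimate, McmcConfig, MODEL_PRIORS, PriorSpec,
                   ValidationError, spawn_seeds)
from .mcmc import _sample_batch
from .scenarios import Scenario, _simulate_arrays

#: method keys accepted by run_benchmark: Bayesian prior configurations plus
#: the non-MCMC approaches.
BAYES_METHODS = tuple(MODEL_PRIORS)
OTHER_METHODS = ("eb", "glmm", "exact", "byar")


@dataclass(frozen=True)
class BenchmarkRow:
    method: str
    coverage_mean: float
    coverage_sd: float
    width_mean: float
    width_sd: float
    rmse_mean: float
    rmse_sd: float
    n_failed: int = 0


def evaluate_interval(interval: IntervalEstimate, truth_lambda: float
                      ) -> tuple[int, float, float]:
    """(covered, width, squared error) for one interval against the truth.

    Coverage uses the closed interval: boundary hits count as covered.
    """
    covered = int(interval.lower <= truth_lambda <= interval.upper)
    width = interval.upper - interval.lower
    sq_error = (interval.point - truth_lambda) ** 2
    return covered, width, sq_error


def run_benchmark(scenario: Scenario, methods, n_reps: int,
                  mcmc: McmcConfig | None = None, seed: int = 0,
                  level: float = 0.95, chunk: int = 50,
                  rmse_per_interval: bool = False) -> pd.DataFrame:
    """Run the simulation study for one scenario.

    Returns a DataFrame with one :class:`BenchmarkRow` per method.  Fit
    failures (possible for the empirical Bayes fit on an all-zero replicate)
    drop that replicate for that method only; the exclusion count is
    reported in ``n_failed``.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be at least 2")
    cfg = mcmc if mcmc is not None else McmcConfig()
    seeds = spawn_seeds(seed, 1 + len(methods))
    E = np.asarray(scenario.expected, dtype=float)
    I = E.size
    _, _, lam_true, counts = _simulate_arrays(
        scenario.mu0, scenario.sigma0, E, n_reps, seeds[0])

    rows = []
    for k, method in enumerate(methods):
        point, lower, upper, valid = _method_intervals(
            method, counts, E, cfg, seeds[1 + k], level, chunk)
        rows.append(_aggregate(method, point, lower, upper, lam_true,
                               valid, rmse_per_interval))
    return pd.DataFrame([asdict(r) for r in rows])


def _method_intervals(method: str, counts: np.ndarray, E: np.ndarray,
                      cfg: McmcConfig, seed: int, level: float, chunk: int):
    """(point, lower, upper) arrays of shape (J, I) plus a per-replicate
    validity mask."""
    J, I = counts.shape
    alpha = 1.0 - level
    valid = np.ones(J, dtype=bool)
    if method in MODEL_PRIORS:
        prior = MODEL_PRIORS[method]
        point, lower, upper = _bayes_summaries(
            counts, E, prior, cfg, seed, level, chunk)
    elif method == "exact":
        lower, upper = classical.exact_poisson_interval(counts, level)
        point = counts.astype(float)
    elif method == "byar":
        lower, upper = classical.byars_interval(counts, level)
        point = counts.astype(float)
    elif method == "eb":
        from scipy import stats
        point = np.empty((J, I))
        lower = np.empty((J, I))
        upper = np.empty((J, I))
        for j in range(J):
            table = _as_table(counts[j], E, j)
            try:
                fit = classical.fit_eb_gamma(table)
            except ValidationError:
                valid[j] = False
                continue
            shape = fit.alpha + counts[j]
            rate = fit.beta + E
            point[j] = E * shape / rate
            lower[j] = E * stats.gamma.ppf(alpha / 2, shape, scale=1 / rate)
            upper[j] = E * stats.gamma.ppf(1 - alpha / 2, shape,
                                           scale=1 / rate)
    elif method == "glmm":
        point = np.empty((J, I))
        lower = np.empty((J, I))
        upper = np.empty((J, I))
        for j in range(J):
            table = _as_table(counts[j], E, j)
            try:
                fit = classical.fit_glmm_ml(table)
                ivs = classical.glmm_intervals(fit, table, level)
            except (ValidationError, FloatingPointError):
                valid[j] = False
                continue
            point[j] = [iv.point for iv in ivs]
            lower[j] = [iv.lower for iv in ivs]
            upper[j] = [iv.upper for iv in ivs]
    else:
        raise ValidationError(f"unknown method {method!r}")
    return point, lower, upper, valid


def _bayes_summaries(counts: np.ndarray, E: np.ndarray, prior: PriorSpec,
                     cfg: McmcConfig, seed: int, level: float, chunk: int):
    """Posterior mean and equal-tail quantiles of lambda for every replicate,
    computed chunk-by-chunk through the batch sampler."""
    J, I = counts.shape
    alpha = 1.0 - level
    point = np.empty((J, I))
    lower = np.empty((J, I))
    upper = np.empty((J, I))
    chunk_seeds = spawn_seeds(seed, (J + chunk - 1) // chunk)
    for c, start in enumerate(range(0, J, chunk)):
        sl = slice(start, min(start + chunk, J))
        nrep = sl.stop - sl.start
        C = np.repeat(counts[sl], cfg.n_chains, axis=0)
        Eb = np.broadcast_to(E, (nrep * cfg.n_chains, I))
        draws = _sample_batch(C, Eb, prior, cfg, seed=chunk_seeds[c])
        S = draws["mu"].shape[1]
        mu = draws["mu"].reshape(nrep, cfg.n_chains * S)
        nu = draws["nu"].reshape(nrep, cfg.n_chains * S, I)
        lam = np.exp(mu[:, :, None] + nu) * E[None, None, :]
        point[sl] = lam.mean(axis=1)
        lower[sl] = np.quantile(lam, alpha / 2, axis=1)
        upper[sl] = np.quantile(lam, 1 - alpha / 2, axis=1)
    return point, lower, upper


def _as_table(counts_row, E, j):
    from .data import CountTable
    I = len(counts_row)
    return CountTable(entity_id=f"rep{j}",
                      area_ids=tuple(f"A{i:02d}" for i in range(I)),
                      observed=counts_row, expected=E)


def _aggregate(method, point, lower, upper, lam_true, valid,
               rmse_per_interval) -> BenchmarkRow:
    if not valid.any():
        raise ValidationError(f"method {method!r} failed on every replicate")
    pt, lo, hi, lt = (a[valid] for a in (point, lower, upper, lam_true))
    if not np.all(np.isfinite(hi)):
        raise ValidationError(f"method {method!r} produced non-finite widths")
    covered = ((lo <= lt) & (lt <= hi)).astype(float).ravel() * 100.0
    widths = (hi - lo).ravel()
    sq = (pt - lt) ** 2
    if rmse_per_interval:
        rmse = np.sqrt(sq.ravel())
    else:
        rmse = np.sqrt(sq.mean(axis=1))
    return BenchmarkRow(
        method=method,
        coverage_mean=float(covered.mean()),
        coverage_sd=float(covered.std(ddof=1)),
        width_mean=float(widths.mean()),
        width_sd=float(widths.std(ddof=1)),
        rmse_mean=float(rmse.mean()),
        rmse_sd=float(rmse.std(ddof=1)),
        n_failed=int((~valid).sum()),
    )
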