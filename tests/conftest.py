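"""Shared fixtures: deterministic tables, replicates and posterior stubs."""

from __future__ import annotations

import numpy as np
import pytest

import rarerates as rr
from rarerates.mcmc import PosteriorFit


def make_table(observed, expected, entity_id="test"):
    observed = np.asarray(observed)
    expected = np.asarray(expected, dtype=float)
    return rr.CountTable(
        entity_id=entity_id,
        area_ids=tuple(f"A{i:02d}" for i in range(len(observed))),
        observed=observed,
        expected=expected,
    )


class _StubTable:
    """Duck-typed count table for hand examples (allows a single area)."""

    def __init__(self, observed, expected):
        self.entity_id = "stub"
        self.observed = np.asarray(observed, dtype=np.int64)
        self.expected = np.asarray(expected, dtype=float)
        self.area_ids = tuple(f"A{i:02d}" for i in range(len(self.observed)))
        self.n_areas = len(self.observed)


def make_fit(counts, expected, lam_draws, prior=None):
    """PosteriorFit stub with prescribed lambda draws (mu fixed at 0)."""
    lam_draws = np.atleast_2d(np.asarray(lam_draws, dtype=float))
    expected = np.asarray(expected, dtype=float)
    table = _StubTable(counts, expected)
    nu = np.log(lam_draws / expected[None, :])
    return PosteriorFit(
        draws_mu=np.zeros(lam_draws.shape[0]),
        draws_sigma=np.ones(lam_draws.shape[0]),
        draws_nu=nu,
        draws_lambda=lam_draws,
        prior=prior or rr.PriorSpec.uniform(0, 500),
        data=table,
        diagnostics={},
    )


@pytest.fixture(scope="session")
def homog_table():
    """27 areas, every observed and expected count equal to 1000."""
    return make_table(np.full(27, 1000), np.full(27, 1000.0), "homog")


@pytest.fixture(scope="session")
def recovery_table():
    """One replicate generated with mu0=0, sigma0=0.5, E_i=3000, I=27."""
    ds = rr.simulate_replicates(0.0, 0.5, np.full(27, 3000.0), 1, seed=42)[0]
    return ds.to_table("recovery")


@pytest.fixture(scope="session")
def sparse_table():
    """One middle-ear-like replicate (near-zero counts)."""
    scen = rr.preset_scenario("middle_ear")
    ds = rr.simulate_replicates(scen.mu0, scen.sigma0, scen.expected,
                                1, seed=99)[0]
    return ds.to_table("sparse")


@pytest.fixture(scope="session")
def quick_cfg():
    """Short chains for unit tests (acceptance tests use the defaults)."""
    return rr.McmcConfig(n_chains=2, n_iter=2000, n_burnin=1000, seed=3)
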