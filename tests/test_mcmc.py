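"""Sampler correctness: densities, conditional laws, intervals, diagnostics.

The heavier checks validate the sampler against independent references: the
probability-integral transform of the precision's conjugate conditional,
arviz's split-R-hat/ESS, and a JAGS fit of the same model on the same data.
"""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

import rarerates as rr
from rarerates import ValidationError
from rarerates.mcmc import log_joint, poisson_loglik, rhat_ess

from conftest import make_fit, make_table


class TestLogJoint:
    def test_poisson_term_hand_values(self):
        # log P(0 | lam=1) = -1 ; log P(2 | lam=1) = -1 - log 2
        assert poisson_loglik([0], [1.0], 0.0, [0.0]) == pytest.approx(-1.0)
        assert poisson_loglik([2], [1.0], 0.0, [0.0]) == pytest.approx(
            -1.6931471805599454)

    def test_outside_support_is_minus_inf(self):
        table = make_table([1, 2], [1.0, 1.0])
        prior = rr.PriorSpec.uniform(1.0, 500.0)
        assert log_joint(table, 0.0, [0.0, 0.0], 0.5, prior) == -np.inf
        assert log_joint(table, 0.0, [0.0, 0.0], -1.0, prior) == -np.inf

    def test_decomposes_into_likelihood_prior_terms(self):
        table = make_table([3, 0], [2.0, 1.5])
        prior = rr.PriorSpec.uniform(0.0, 500.0)
        mu, nu, sigma = 0.2, np.array([0.1, -0.3]), 0.7
        expected = (poisson_loglik(table.observed, table.expected, mu, nu)
                    + stats.norm.logpdf(nu, 0, sigma).sum()
                    - np.log(500.0))
        assert log_joint(table, mu, nu, sigma, prior) == pytest.approx(expected)


class TestFitBayes:
    def test_no_heterogeneity_recovery(self, homog_table):
        fit = rr.fit_bayes(homog_table, rr.PriorSpec.uniform(0, 500),
                           rr.McmcConfig(seed=1))
        assert abs(fit.draws_mu.mean()) < 0.05
        assert fit.draws_sigma.mean() < 0.1

    def test_support_constraint_respected(self, homog_table, quick_cfg):
        fit = rr.fit_bayes(homog_table, rr.PriorSpec.uniform(1.0, 500),
                           quick_cfg)
        assert fit.draws_sigma.min() >= 1.0

    def test_lambda_draw_identity(self, sparse_table, quick_cfg):
        fit = rr.fit_bayes(sparse_table, rr.PriorSpec.uniform(0, 500),
                           quick_cfg)
        recon = np.exp(fit.draws_mu[:, None] + fit.draws_nu) \
            * sparse_table.expected[None, :]
        assert np.allclose(fit.draws_lambda, recon)

    def test_draw_count_contract(self, sparse_table):
        cfg = rr.McmcConfig(n_chains=3, n_iter=900, n_burnin=300, thin=3,
                            seed=5)
        fit = rr.fit_bayes(sparse_table, rr.PriorSpec.uniform(0, 500), cfg)
        assert fit.n_draws == 3 * (900 // 3)

    def test_hierarchical_bounds_bracket_sigma(self, sparse_table, quick_cfg):
        fit = rr.fit_bayes(sparse_table, rr.PriorSpec.hierarchical(),
                           quick_cfg)
        assert np.all(fit.draws_lb <= fit.draws_sigma + 1e-12)
        assert np.all(fit.draws_sigma <= fit.draws_ub + 1e-12)
        assert fit.draws_lb.min() >= 0 and fit.draws_lb.max() <= 5.0
        assert fit.draws_ub.max() <= 500.0

    def test_exchangeability_of_lambda_summaries(self, sparse_table,
                                                 quick_cfg):
        # permuting input rows permutes the lambda summaries (MC tolerance)
        perm = [5, 3, 11, 0, 1, 2, 4, 6, 7, 8, 9, 10] + list(range(12, 27))
        prior = rr.PriorSpec.uniform(0, 500)
        fit = rr.fit_bayes(sparse_table, prior, quick_cfg)
        fit_p = rr.fit_bayes(sparse_table.permuted(perm), prior, quick_cfg)
        lam = fit.draws_lambda.mean(axis=0)[perm]
        lam_p = fit_p.draws_lambda.mean(axis=0)
        assert np.allclose(lam, lam_p, rtol=0.05, atol=0.05)

    def test_gamma_precision_conditional_law(self, sparse_table):
        """PIT check of tau | nu ~ Gamma(shape + I/2, rate + sum(nu^2)/2).

        In equilibrium the conditional law of the precision given the random
        effects is the conjugate gamma; its probability-integral transform
        over kept draws must be uniform (KS at alpha = 0.001, thinned draws).
        """
        prior = rr.PriorSpec.gamma(1.0, 1.0)  # proper prior: clean equilibrium
        cfg = rr.McmcConfig(n_chains=2, n_iter=5000, n_burnin=2000, thin=2,
                            seed=17)
        fit = rr.fit_bayes(sparse_table, prior, cfg)
        tau = fit.draws_sigma ** -2.0
        ss = (fit.draws_nu ** 2).sum(axis=1)
        shape = prior.gamma_shape + sparse_table.n_areas / 2.0
        pit = stats.gamma.cdf(tau, shape, scale=1.0 / (prior.gamma_rate
                                                       + 0.5 * ss))
        assert stats.kstest(pit, "uniform").pvalue > 0.001

    def test_overflowing_inputs_raise_initialization_error(self):
        table = make_table([0, 0], [1e308, 1e308])
        with pytest.raises(ValidationError, match="log-joint"):
            rr.fit_bayes(table, rr.PriorSpec.uniform(0, 500),
                         rr.McmcConfig(n_iter=10, n_burnin=0))


class TestLambdaIntervals:
    def test_constant_draws(self):
        fit = make_fit([5, 5], [1.0, 1.0], np.full((200, 2), 7.0))
        ivs = rr.lambda_intervals(fit, 0.95)
        assert all(iv.lower == iv.upper == iv.point == 7.0 for iv in ivs)

    def test_quantile_convention_on_1_to_100(self):
        draws = np.arange(1.0, 101.0)[:, None]
        fit = make_fit([5], [1.0], np.hstack([draws, draws]))
        iv = rr.lambda_intervals(fit, 0.95)[0]
        # linear-interpolation empirical quantiles of {1..100}
        assert iv.lower == pytest.approx(3.475)
        assert iv.upper == pytest.approx(97.525)
        assert iv.point == pytest.approx(50.5)

    def test_invalid_level_rejected(self):
        fit = make_fit([5], [1.0], np.ones((200, 1)))
        with pytest.raises(ValidationError):
            rr.lambda_intervals(fit, 1.2)

    def test_too_few_draws_rejected(self):
        fit = make_fit([5], [1.0], np.ones((50, 1)))
        with pytest.raises(ValidationError):
            rr.lambda_intervals(fit, 0.95)


class TestDiagnostics:
    def test_constant_chains_rhat_one(self):
        rhat, _ = rhat_ess(np.ones((2, 100)))
        assert rhat == 1.0

    def test_well_mixed_chains(self):
        rng = np.random.default_rng(0)
        rhat, ess = rhat_ess(rng.standard_normal((2, 5000)))
        assert rhat < 1.01
        assert ess > 5000  # independent draws

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.standard_normal(500),
                           rng.standard_normal(500) + 5.0])
        rhat, _ = rhat_ess(chains)
        assert rhat > 1.5

    def test_single_chain_gives_ess_only(self):
        rng = np.random.default_rng(2)
        rhat, ess = rhat_ess(rng.standard_normal((1, 1000)))
        assert np.isnan(rhat)
        assert ess > 0

    def test_against_arviz(self):
        import arviz as az
        rng = np.random.default_rng(3)
        # AR(1) chains so the ESS is materially below the draw count
        x = np.empty((2, 4000))
        x[:, 0] = rng.standard_normal(2)
        eps = rng.standard_normal((2, 4000))
        for t in range(1, 4000):
            x[:, t] = 0.7 * x[:, t - 1] + eps[:, t]
        rhat, ess = rhat_ess(x)
        assert rhat == pytest.approx(float(az.rhat(x)), abs=0.01)
        assert ess == pytest.approx(float(az.ess(x)), rel=0.25)


_JAGS_SCRIPT = textwrap.dedent("""
    library(rjags)
    d <- read.csv("%(csv)s")
    C <- d$observed; E <- d$expected; I <- length(C)
    model <- textConnection("model {
      for (i in 1:I) {
        C[i] ~ dpois(lambda[i])
        lambda[i] <- exp(mu + nu[i]) * E[i]
        nu[i] ~ dnorm(0, tau)
      }
      mu ~ dnorm(0, 1.0E-6)
      sigma ~ dunif(0, 500)
      tau <- 1/(sigma*sigma)
    }")
    jm <- jags.model(model, data=list(C=C, E=E, I=I), n.chains=2, quiet=TRUE)
    update(jm, 4000, progress.bar="none")
    s <- as.matrix(coda.samples(jm, c("lambda", "sigma"), 15000,
                                progress.bar="none"))
    lam <- s[, grep("^lambda", colnames(s))]
    w <- apply(lam, 2, function(x) diff(quantile(x, c(0.025, 0.975))))
    cat(mean(w), mean(s[, "sigma"]), sep="\\n")
""")


class TestAgainstJags:
    def test_credible_widths_match_jags(self, sparse_table, tmp_path):
        """Independent MCMC engine (JAGS) on the same sparse table and
        Uniform(0,500) prior: mean CrI width and posterior sigma agree."""
        csv = tmp_path / "tab.csv"
        rr.write_count_table(sparse_table, csv)
        script = tmp_path / "fit.R"
        script.write_text(_JAGS_SCRIPT % {"csv": str(csv)})
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        jags_width, jags_sigma = map(float, proc.stdout.strip().split()[-2:])

        fit = rr.fit_bayes(sparse_table, rr.PriorSpec.uniform(0, 500),
                           rr.McmcConfig(seed=5))
        width = np.mean([iv.width for iv in rr.lambda_intervals(fit)])
        assert width == pytest.approx(jags_width, rel=0.06)
        assert fit.draws_sigma.mean() == pytest.approx(jags_sigma, abs=0.06)
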