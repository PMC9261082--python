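import dataclasses

import numpy as np
import pytest
from scipy import stats

import famliab as fl
from famliab.inference import DegenerateCohortError, McmcConfig
from famliab._utils import std_truncnorm_lower, substream


@pytest.fixture(scope="module")
def lm0_sim():
    truth = fl.TruthConfig(n_families=600, n_counties=30,
                           sigma2={"h": 0.5, "e": 0.5}, seed=19)
    cohort, eqi, _ = fl.simulate_cohort(truth)
    return truth, cohort, eqi


@pytest.fixture(scope="module")
def lm0_fit(lm0_sim):
    _, cohort, eqi = lm0_sim
    cfg = McmcConfig(n_chains=2, n_warmup=300, n_samples=200, seed=2)
    return fl.fit(cohort, eqi, fl.get_model_spec("LM0"), cfg=cfg)


class TestTruncatedNormal:
    def test_respects_bound_and_moments(self):
        rng = substream(0, "t")
        for alpha in (-2.0, 0.0, 1.5, 8.0):
            draws = std_truncnorm_lower(np.full(40_000, alpha), rng)
            assert (draws >= alpha).all()
            expected = stats.truncnorm.mean(alpha, np.inf)
            assert abs(draws.mean() - expected) < 0.02


class TestFit:
    def test_seeded_determinism(self, lm0_sim):
        _, cohort, eqi = lm0_sim
        cfg = McmcConfig(n_chains=2, n_warmup=60, n_samples=100, seed=5)
        d1 = fl.fit(cohort, eqi, fl.get_model_spec("LM0"), cfg=cfg)
        d2 = fl.fit(cohort, eqi, fl.get_model_spec("LM0"), cfg=cfg)
        assert np.array_equal(d1.beta, d2.beta)
        for c in d1.sigma:
            assert np.array_equal(d1.sigma[c], d2.sigma[c])
        assert np.array_equal(d1.pointwise_loglik, d2.pointwise_loglik)

    def test_degenerate_cohort_refused(self, lm0_sim):
        _, cohort, eqi = lm0_sim
        df = cohort.df.copy()
        df["dx_code_count"] = 0
        zero = fl.Cohort(df)
        with pytest.raises(DegenerateCohortError):
            fl.fit(zero, eqi, fl.get_model_spec("LM0"))

    def test_hmc_backend_is_declared_contract(self, lm0_sim):
        _, cohort, eqi = lm0_sim
        cfg = McmcConfig(sampler="hmc")
        with pytest.raises(NotImplementedError):
            fl.fit(cohort, eqi, fl.get_model_spec("LM0"), cfg=cfg)

    def test_lm0_recovery_small(self, lm0_fit, lm0_sim):
        """Posterior mean h2 within 3 posterior SDs of the generating 0.5."""
        truth, _, _ = lm0_sim
        sig2 = {k: v.reshape(-1) ** 2 for k, v in lm0_fit.sigma.items()}
        h2 = sig2["h"] / (sig2["h"] + sig2["e"])
        assert abs(h2.mean() - 0.5) < 3 * h2.std()
        assert h2.std() < 0.25  # posterior is informative, not prior-wide

    def test_loglik_shape_and_finiteness(self, lm0_fit, lm0_sim):
        _, cohort, _ = lm0_sim
        ll = lm0_fit.loglik_matrix()
        assert ll.shape == (2 * 200, cohort.n_individuals)
        assert np.isfinite(ll).all()
        assert (ll < 0).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1)
        with pytest.raises(ValueError):
            McmcConfig(n_chains=2, n_samples=50)
        with pytest.raises(ValueError):
            McmcConfig(sampler="nuts")


class TestPriorSampling:
    def test_prior_marginals_match_half_normal(self, lm0_sim):
        """With the likelihood disabled the sampler's scale marginals must
        reproduce their half-normal priors (Kolmogorov-Smirnov, generous)."""
        _, cohort, eqi = lm0_sim
        cfg = McmcConfig(n_chains=2, n_warmup=100, n_samples=1500, seed=3)
        draws = fl.fit(cohort, eqi, fl.get_model_spec("LM0"), cfg=cfg,
                       prior_only=True)
        for comp in ("h", "e"):
            mags = np.abs(draws.sigma[comp].reshape(-1))
            ks = stats.kstest(mags, "halfnorm")
            assert ks.pvalue > 1e-4, (comp, ks)

    def test_prior_beta_scale(self, lm0_sim):
        _, cohort, eqi = lm0_sim
        cfg = McmcConfig(n_chains=2, n_warmup=50, n_samples=800, seed=4)
        draws = fl.fit(cohort, eqi, fl.get_model_spec("LM0"), cfg=cfg,
                       prior_only=True)
        b = draws.beta[:, :, 0].reshape(-1)
        assert abs(b.std() - 5.0) < 0.5


class TestConvergenceReport:
    def test_healthy_chains_pass(self):
        rng = np.random.default_rng(0)
        d = _fake_draws(rng.standard_normal((2, 400)))
        rep = fl.convergence_report(d)
        assert rep.passed
        assert rep.table.loc["sigma2[h]", "r_hat"] < 1.05

    def test_shifted_chain_fails(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, 400))
        arr[1] += 3.0
        rep = fl.convergence_report(_fake_draws(arr))
        assert not rep.passed
        assert rep.table.loc["sigma2[h]", "r_hat"] > 1.1

    def test_constant_chains_reported_undefined(self):
        rep = fl.convergence_report(_fake_draws(np.ones((2, 400))))
        assert not rep.passed
        assert np.isnan(rep.table.loc["sigma2[h]", "r_hat"])

    def test_single_chain_error(self):
        d = _fake_draws(np.random.default_rng(2).standard_normal((2, 300)))
        d.beta = d.beta[:1]
        with pytest.raises(ValueError, match="2 chains"):
            fl.convergence_report(d)


def _fake_draws(sigma_h):
    """PosteriorDraws shell around externally constructed sigma_h chains."""
    from famliab.inference import PosteriorDraws, _diagnostics

    C, D = sigma_h.shape
    rng = np.random.default_rng(99)
    beta = rng.standard_normal((C, D, 1))
    sigma = {"h": sigma_h, "e": np.abs(rng.standard_normal((C, D))) + 0.5}
    diag = _diagnostics(beta, ["intercept"], sigma, None)
    return PosteriorDraws(
        spec=fl.get_model_spec("LM0"), beta=beta, beta_names=["intercept"],
        sigma=sigma, spline=None, spline_basis=None, tau=None,
        pointwise_loglik=None, diagnostics=diag,
        converged=bool((diag["r_hat"] <= 1.1).all()), meta={})


class TestSimulationBasedCalibration:
    def test_rank_statistics_uniform(self):
        """SBC at small scale: when every parameter (scales and fixed
        effects alike) is drawn from the prior the fit uses, the rank of
        the true h2 fraction within thinned posterior draws is uniform
        over replicates."""
        rng = np.random.default_rng(55)
        n_rep, n_keep = 18, 19
        priors = fl.PriorSpec(beta_scale=1.0)
        ranks = []
        for rep in range(n_rep):
            sh = abs(rng.standard_normal())          # half-normal(1) truth
            se = abs(rng.standard_normal()) + 1e-3
            truth = fl.TruthConfig(
                n_families=300, n_counties=15,
                sigma2={"h": sh**2, "e": se**2}, seed=1000 + rep,
                intercept=rng.standard_normal(),
                beta_sex=rng.standard_normal(),
                beta_age=rng.standard_normal())
            cohort, eqi, _ = fl.simulate_cohort(truth)
            if cohort.n_cases in (0, cohort.n_individuals):
                continue
            cfg = McmcConfig(n_chains=2, n_warmup=300, n_samples=100,
                             seed=rep, store_loglik=False)
            d = fl.fit(cohort, eqi, fl.get_model_spec("LM0"), priors, cfg)
            sig2 = {k: v.reshape(-1) ** 2 for k, v in d.sigma.items()}
            h2 = sig2["h"] / (sig2["h"] + sig2["e"])
            h2 = h2[:: len(h2) // n_keep][:n_keep]   # thin to weaken autocorr
            true_h2 = sh**2 / (sh**2 + se**2)
            ranks.append((h2 < true_h2).sum())
        counts = np.bincount(np.array(ranks) // 5, minlength=4)[:4]
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        # 3 dof; reject only at extreme evidence of miscalibration
        assert stats.chi2.sf(chi2, df=3) > 1e-3, counts
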