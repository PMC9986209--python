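"""Sampler building blocks, diagnostics, and small end-to-end MCMC runs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from emadsem.dsem import (
    DynamicSEM,
    MCMCConfig,
    psr,
    run_mcmc,
    sample_latent_states,
    sample_random_effects,
    var_regression_posterior,
    within_model_loglik,
)
from emadsem.synthetic import (
    DesignConfig,
    RandomEffectVector,
    simulate_dataset,
    simulate_person_series,
    stationary_covariance,
)
from emadsem.timegrid import align_dataset


class TestWithinLoglik:
    def test_standard_normal_at_origin(self):
        # T transitions of a bivariate standard normal at zero
        re = RandomEffectVector(0, 0, 0, 0, 0, 0)
        vals = np.zeros((11, 2))
        ll = within_model_loglik(vals, re, np.eye(2))
        assert ll == pytest.approx(-10 * np.log(2 * np.pi))

    def test_single_transition_hand_computed(self):
        re = RandomEffectVector(1.0, 2.0, 0.5, 0.3, 0.1, -0.2)
        sigma = np.array([[1.2, 0.3], [0.3, 0.9]])
        vals = np.array([[2.0, 3.5], [1.4, 2.2]])
        d = vals - np.array([1.0, 2.0])
        mean = re.phi_matrix @ d[0]
        expected = multivariate_normal.logpdf(d[1], mean, sigma)
        assert within_model_loglik(vals, re, sigma) == pytest.approx(expected)

    def test_invariant_to_joint_shift(self):
        re = RandomEffectVector(0.0, 0.0, 0.4, 0.2, 0.0, 0.1)
        vals = np.random.default_rng(0).normal(size=(20, 2))
        base = within_model_loglik(vals, re, np.eye(2))
        shifted = RandomEffectVector(5.0, -3.0, 0.4, 0.2, 0.0, 0.1)
        assert within_model_loglik(vals + [5.0, -3.0], shifted, np.eye(2)) == pytest.approx(base)

    def test_missing_slots_contribute_nothing(self):
        re = RandomEffectVector(0, 0, 0, 0, 0, 0)
        vals = np.zeros((5, 2))
        vals[2] = np.nan  # breaks both adjacent transitions
        ll = within_model_loglik(vals, re, np.eye(2))
        assert ll == pytest.approx(-2 * np.log(2 * np.pi))

    def test_singular_sigma_rejected(self):
        re = RandomEffectVector(0, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            within_model_loglik(np.zeros((3, 2)), re, np.zeros((2, 2)))


class TestConjugatePosterior:
    def test_scalar_ar1_closed_form(self, rng):
        # y_t = phi x_t + e, known sigma^2: posterior precision and mean
        phi_true, sig2, v0, m0 = 0.6, 0.8, 4.0, 0.1
        x = rng.normal(size=(200, 1))
        y = phi_true * x + rng.normal(scale=np.sqrt(sig2), size=(200, 1))
        mean, cov = var_regression_posterior(
            x, y, [[sig2]], np.array([m0]), np.array([[v0]])
        )
        prec = (x**2).sum() / sig2 + 1 / v0
        m = ((x * y).sum() / sig2 + m0 / v0) / prec
        assert mean[0] == pytest.approx(m)
        assert cov[0, 0] == pytest.approx(1 / prec)

    def test_bivariate_matches_gls(self, rng):
        sigma = np.array([[1.0, 0.4], [0.4, 2.0]])
        x = rng.normal(size=(500, 2))
        b = np.array([[0.5, 0.2], [0.1, 0.3]])
        y = x @ b.T + rng.multivariate_normal([0, 0], sigma, size=500)
        mean, cov = var_regression_posterior(
            x, y, sigma, np.zeros(4), np.eye(4) * 1e6
        )
        # with a flat prior the posterior mean is the (equation-wise) OLS
        bhat = np.linalg.lstsq(x, y, rcond=None)[0].T
        np.testing.assert_allclose(mean.reshape(2, 2), bhat, atol=1e-6)


class TestLatentStates:
    re = RandomEffectVector(0, 0, 0.5, 0.3, 0.1, 0.2)
    sigma = np.array([[1.0, 0.2], [0.2, 1.5]])

    def test_no_missing_passthrough(self, rng):
        vals = rng.normal(size=(10, 2)) + 0.0
        out = sample_latent_states(vals, self.re, self.sigma, rng)
        np.testing.assert_array_equal(out, vals)

    def test_single_missing_matches_brute_force_conditioning(self, rng):
        """Full-conditional draw vs conditioning of the 6-dim joint."""
        phi = self.re.phi_matrix
        v = stationary_covariance(phi, self.sigma)
        # joint covariance of (d0, d1, d2), stationary VAR(1)
        big = np.zeros((6, 6))
        lags = {0: v, 1: phi @ v, 2: phi @ phi @ v}
        for s in range(3):
            for t in range(3):
                block = lags[abs(s - t)]
                big[2 * s: 2 * s + 2, 2 * t: 2 * t + 2] = (
                    block.T if s < t else block
                )
        d0, d2 = np.array([1.0, -0.5]), np.array([0.4, 0.8])
        known = np.concatenate([d0, d2])
        kk = np.ix_([0, 1, 4, 5], [0, 1, 4, 5])
        ku = np.ix_([2, 3], [0, 1, 4, 5])
        sol = big[ku] @ np.linalg.inv(big[kk])
        mean_oracle = sol @ known
        cov_oracle = big[2:4, 2:4] - sol @ big[ku].T

        vals = np.array([d0, [np.nan, np.nan], d2])
        draws = np.stack([
            sample_latent_states(vals.copy(), self.re, self.sigma,
                                 np.random.default_rng(i))[1]
            for i in range(4000)
        ])
        se = np.sqrt(np.diag(cov_oracle) / 4000)
        np.testing.assert_allclose(draws.mean(0), mean_oracle,
                                   atol=float(4 * se.max()))
        np.testing.assert_allclose(np.cov(draws.T), cov_oracle, atol=0.15)

    def test_long_gap_variance_approaches_stationary(self):
        """Deep inside an all-missing stretch the Gibbs equilibrium has the
        stationary (Lyapunov) variance."""
        v = stationary_covariance(self.re.phi_matrix, self.sigma)
        t_n = 32
        vals = np.full((t_n, 2), np.nan)
        vals[0] = [0.5, 0.5]
        vals[-1] = [-0.5, 1.0]
        mid = []
        for i in range(250):
            out = sample_latent_states(vals.copy(), self.re, self.sigma,
                                       np.random.default_rng(i), n_scans=60)
            mid.append(out[t_n // 2])
        var_mid = np.var(np.stack(mid), axis=0)
        np.testing.assert_allclose(var_mid, np.diag(v), rtol=0.30)

    def test_needs_one_observation(self):
        with pytest.raises(ValueError):
            sample_latent_states(np.full((4, 2), np.nan), self.re, self.sigma)


class TestSampleRandomEffects:
    def test_all_missing_falls_back_to_prior(self):
        prior_mean = np.array([9.0, 14.0, 0.3, 0.2, 0.0, 0.1])
        prior_sd = np.array([1.0, 1.0, 0.1, 0.1, 0.05, 0.05])
        vals = np.full((20, 2), np.nan)
        vals[0] = [9.0, 14.0]
        vals[1:] = np.nan
        # one observation -> fewer than 3 transitions -> prior draw
        draws = np.stack([
            sample_random_effects(vals, prior_mean, prior_sd, np.eye(2),
                                  np.random.default_rng(i)).as_array()
            for i in range(3000)
        ])
        np.testing.assert_allclose(draws.mean(0), prior_mean,
                                   atol=float(4 * prior_sd.max() / np.sqrt(3000)))
        np.testing.assert_allclose(draws.std(0), prior_sd, rtol=0.12)

    def test_long_series_concentrates_on_ols(self, rng):
        re_true = RandomEffectVector(0.0, 0.0, 0.5, 0.3, 0.1, -0.1)
        sigma = np.eye(2)
        d = simulate_person_series(re_true, sigma, 5000, rng)
        prior_mean = np.zeros(6)
        prior_sd = np.array([5.0, 5.0, 1.0, 1.0, 1.0, 1.0])
        draws = np.stack([
            sample_random_effects(d, prior_mean, prior_sd, sigma,
                                  np.random.default_rng(i)).as_array()
            for i in range(300)
        ])
        x, y = d[:-1], d[1:]
        bhat = np.linalg.lstsq(x, y, rcond=None)[0].T  # rows = equations
        ols = np.array([bhat[0, 0], bhat[1, 1], bhat[0, 1], bhat[1, 0]])
        np.testing.assert_allclose(draws.mean(0)[2:], ols, atol=0.02)


class TestPSR:
    def test_identical_chains_give_exactly_one(self, rng):
        c = rng.normal(size=(1, 500))
        chains = np.vstack([c, c])
        assert psr(chains)[0] == 1.0

    def test_offset_chains_flagged(self, rng):
        a = rng.normal(size=(1, 500))
        chains = np.vstack([a, a + 50.0])
        assert psr(chains)[0] > 5.0

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(42)
        chains = rng.normal(size=(2, 10_000))
        val = psr(chains)[0]
        assert 1.0 <= val < 1.01

    def test_agrees_with_arviz_on_iid_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        chains = rng.normal(size=(2, 10_000))
        ours = psr(chains)[0]
        theirs = float(
            az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values[0]
        )
        assert abs(ours - theirs) < 0.01

    def test_degenerate_constant_chains(self):
        chains = np.full((2, 100), 3.14)
        assert psr(chains)[0] == 1.0
        chains2 = chains.copy()
        chains2[1] += 1.0
        assert np.isinf(psr(chains2)[0])


@pytest.fixture(scope="module")
def tiny_fit():
    """A small but complete fitted model shared by the smoke tests."""
    ds = simulate_dataset(DesignConfig(n_persons=25, n_days=5, seed=13))
    series = align_dataset(ds.ema)
    est = DynamicSEM(max_iterations=600, min_iterations=600, check_every=300,
                     thinning=5, seed=3)
    est.fit(series, ds.persons)
    return ds, series, est


class TestMCMCRuns:
    def test_seed_determinism(self, tiny_fit):
        ds, series, est = tiny_fit
        est2 = DynamicSEM(max_iterations=600, min_iterations=600,
                          check_every=300, thinning=5, seed=3)
        est2.fit(series, ds.persons)
        np.testing.assert_array_equal(est.draws_.params, est2.draws_.params)
        np.testing.assert_array_equal(
            est.draws_.random_effects, est2.draws_.random_effects
        )

    def test_reference_loadings_exactly_one(self, tiny_fit):
        _, _, est = tiny_fit
        assert (est.draws_.get("lambda_adhd[1]") == 1.0).all()
        assert (est.draws_.get("lambda_int[1]") == 1.0).all()

    def test_draw_bookkeeping(self, tiny_fit):
        _, _, est = tiny_fit
        d = est.draws_
        assert d.n_chains == 2
        # retained = post-burn-in thinned draws
        assert d.n_draws == 600 // 5 // 2
        assert d.params.shape[2] == len(d.names)
        assert len(set(d.names)) == len(d.names)
        assert isinstance(d.converged, bool)
        assert d.n_iterations <= 600

    def test_summary_and_frame(self, tiny_fit):
        _, _, est = tiny_fit
        s = est.summary()
        assert (s["ci_lower"] <= s["ci_upper"]).all()
        frame = est.draws_.to_frame()
        assert {"chain", "draw"} <= set(frame.columns)

    def test_variances_positive_in_all_draws(self, tiny_fit):
        _, _, est = tiny_fit
        d = est.draws_
        for name in d.names:
            if name.startswith(("tau2", "theta", "psi")):
                assert (d.get(name) > 0).all()
        s11 = d.get("sigma_w[s,s]")
        s22 = d.get("sigma_w[a,a]")
        s12 = d.get("sigma_w[s,a]")
        assert ((s11 * s22 - s12**2) > 0).all()

    def test_two_step_mode_runs(self):
        ds = simulate_dataset(DesignConfig(n_persons=15, n_days=4, seed=17))
        series = align_dataset(ds.ema)
        est = DynamicSEM(max_iterations=100, min_iterations=100, check_every=100,
                         thinning=5, seed=1, two_step=True)
        est.fit(series, ds.persons)
        assert est.draws_.params.shape[1] > 0

    def test_covariate_model_adds_blocks(self):
        from emadsem.synthetic import study_truth

        ds = simulate_dataset(DesignConfig(n_persons=20, n_days=4, seed=19),
                              study_truth(covariates=True))
        series = align_dataset(ds.ema)
        est = DynamicSEM(max_iterations=100, min_iterations=100, check_every=100,
                         thinning=5, seed=1, covariates=["sex", "origin", "ses"])
        est.fit(series, ds.persons)
        assert "gamma[phi_ss,ses]" in est.draws_.names
        assert "beta_int[origin]" in est.draws_.names

    def test_run_mcmc_wrapper(self):
        ds = simulate_dataset(DesignConfig(n_persons=15, n_days=4, seed=23))
        series = align_dataset(ds.ema)
        cfg = MCMCConfig(max_iterations=100, min_iterations=100, check_every=100,
                         thinning=5, seed=5)
        draws = run_mcmc(series, ds.persons, cfg)
        assert draws.params.shape[0] == 2

    def test_posterior_contracts_with_more_data(self):
        sds = []
        for n, days in ((15, 4), (60, 14)):
            ds = simulate_dataset(DesignConfig(n_persons=n, n_days=days, seed=29))
            series = align_dataset(ds.ema)
            est = DynamicSEM(max_iterations=800, min_iterations=800,
                             check_every=400, thinning=5, seed=2)
            est.fit(series, ds.persons)
            flat = est.draws_.stacked("alpha[phi_ss]")
            sds.append(flat.std(ddof=1))
        assert sds[1] < sds[0]
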