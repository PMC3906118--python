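"""Posterior sampling engine: diagnostics, summaries, and the two fitters."""

import numpy as np
import pytest
from scipy import stats

import popsync as ps
from popsync.mcmc import _GaussianKalman

from conftest import make_count_panel, make_gaussian_panel


class TestGelmanRubin:
    def test_identical_chains_return_exactly_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=1000)
        assert ps.gelman_rubin(np.vstack([chain, chain])) == 1.0

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.vstack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert ps.gelman_rubin(chains) > 1.1

    def test_matches_textbook_formula_on_hand_case(self):
        chains = np.array([[1.0, 2.0, 3.0, 2.0] * 3,
                           [2.0, 3.0, 4.0, 3.0] * 3])
        m, n = chains.shape
        w = chains.var(axis=1, ddof=1).mean()
        b = n * chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(max(((n - 1) / n * w + b / n) / w, 1.0))
        assert ps.gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            ps.gelman_rubin(np.ones((1, 100)))

    def test_dict_input_maps_per_parameter(self):
        rng = np.random.default_rng(2)
        draws = {"a": rng.normal(size=(2, 100)), "b": rng.normal(size=(2, 100))}
        out = ps.gelman_rubin(draws)
        assert set(out) == {"a", "b"}


class TestSummarize:
    def test_constant_draws_degenerate(self):
        summ = ps.summarize({"x": np.full((2, 50), 3.0)})
        row = summ["x"]
        assert row["mean"] == 3.0 and row["sd"] == 0.0
        assert row["ci2.5"] == row["ci97.5"] == 3.0

    def test_uniform_quantiles(self):
        rng = np.random.default_rng(3)
        summ = ps.summarize({"u": rng.uniform(size=(1, 1_000_000))})
        row = summ["u"]
        assert row["ci2.5"] == pytest.approx(0.025, abs=0.002)
        assert row["ci97.5"] == pytest.approx(0.975, abs=0.002)

    def test_tiny_mean(self):
        assert ps.summarize({"m": np.array([[1.0, 2.0, 3.0]])})["m"]["mean"] == 2.0


class TestKalmanMarginalLikelihood:
    def test_matches_brute_force_joint_mvn(self):
        """The filter's marginal likelihood equals the log-density of the
        records under the analytically assembled joint normal."""
        pan, _ = make_gaussian_panel(n_sites=2, n_times=4, sessions=2,
                                     sigma2_s=0.1, sigma2_gamma=0.05, seed=11)
        spec = ps.GaussianSSMSpec(pan)
        kal = _GaussianKalman(spec)
        idx = spec.index

        def brute(alpha, beta, s2c, s2d, s2g):
            ns, nt = 2, 4
            phi = 1 + beta
            q = s2c * np.ones((ns, ns)) + s2d * np.eye(ns)
            means = [kal.m0]
            for _ in range(1, nt):
                means.append(alpha + phi * means[-1])
            cov = {(0, 0): 25.0 * np.eye(ns)}
            for t in range(1, nt):
                for s in range(t + 1):
                    cov[(s, t)] = (phi ** 2 * cov[(t - 1, t - 1)] + q) if s == t \
                        else cov[(s, t - 1)] * phi
            m = np.concatenate(means)
            big = np.zeros((ns * nt, ns * nt))
            for t in range(nt):
                for s in range(t + 1):
                    big[s * ns:(s + 1) * ns, t * ns:(t + 1) * ns] = cov[(s, t)]
                    big[t * ns:(t + 1) * ns, s * ns:(s + 1) * ns] = cov[(s, t)].T
            h = np.zeros((idx.rec_value.size, ns * nt))
            for r in range(idx.rec_value.size):
                h[r, idx.rec_time[r] * ns + idx.rec_site[r]] = 1.0
            same = (idx.rec_session[:, None] == idx.rec_session[None, :])
            r_mat = s2g * same + np.diag(idx.rec_var)
            return stats.multivariate_normal.logpdf(
                idx.rec_value, h @ m, h @ big @ h.T + r_mat)

        for pars in [(0.3, -0.4, 0.02, 0.01, 0.05), (0.0, -0.9, 0.1, 0.1, 0.2)]:
            assert kal.loglik(*pars) == pytest.approx(brute(*pars), rel=1e-9)


class TestGaussianFit:
    def test_seeded_determinism(self):
        pan, _ = make_gaussian_panel(n_times=12, seed=20)
        spec = ps.GaussianSSMSpec(pan)
        cfg = ps.MCMCConfig(n_chains=1, n_iter=600, n_burnin=200, thin=2, seed=5)
        a = ps.fit(spec, cfg, save_latents=False)
        b = ps.fit(spec, cfg, save_latents=False)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_informative_panel_recovers_truth(self):
        """Low observation noise, T = 40: 95% CIs cover the generating
        parameters and the posterior concentrates near them."""
        pan, _ = make_gaussian_panel(n_sites=3, n_times=40, sessions=2,
                                     sigma2_s=0.01, sigma2_gamma=0.005, seed=21)
        spec = ps.GaussianSSMSpec(pan)
        res = ps.fit(spec, ps.MCMCConfig(n_chains=2, n_iter=4000, n_burnin=1500,
                                         thin=3, seed=6), save_latents=True)
        truth = {"alpha": 0.25, "beta": -0.26, "sigma2_c": 0.0344,
                 "sigma2_d": 0.0056, "rho": 0.86}
        for name, value in truth.items():
            row = res.summary[name]
            assert row["ci2.5"] - 0.02 <= value <= row["ci97.5"] + 0.02, name
        assert res.summary["rho"]["mean"] == pytest.approx(0.86, abs=0.12)
        # latent residual correlations reflect the strong shared signal
        mat = ps.residual_corr_matrix(res.residual_means())
        off = mat[np.triu_indices(3, 1)]
        assert off.mean() > 0.6

    def test_near_noiseless_posterior_collapses_on_observations(self):
        # replicated identical sessions pin the session-effect variance at
        # zero, so the posterior latent collapses onto the observations
        pan, states = make_gaussian_panel(n_sites=2, n_times=10, sessions=3,
                                          sigma2_s=1e-6, sigma2_gamma=0.0, seed=22)
        spec = ps.GaussianSSMSpec(pan)
        res = ps.fit(spec, ps.MCMCConfig(n_chains=1, n_iter=1500, n_burnin=500,
                                         thin=2, seed=7))
        grid = pan.site_time_means().pivot(index="site", columns="time",
                                           values="value").to_numpy()
        np.testing.assert_allclose(res.latent_means(), grid, atol=0.02)
        assert res.x_draws.std(axis=(0, 1)).max() < 0.02

    def test_prior_predictive_returns_prior_synchrony(self):
        """With no observations the posterior is the prior: the implied
        prior on rho is symmetric around 1/2."""
        import pandas as pd
        empty = ps.ObservationPanel(
            pd.DataFrame(columns=["site", "time", "session", "replicate",
                                  "value", "kind", "sampling_sd", "log_distance"]),
            site_list=["a", "b"], time_grid=[1, 2, 3, 4, 5])
        spec = ps.GaussianSSMSpec(empty)
        res = ps.fit(spec, ps.MCMCConfig(n_chains=3, n_iter=4000, n_burnin=1000,
                                         thin=2, seed=8), save_latents=False)
        assert res.summary["rho"]["mean"] == pytest.approx(0.5, abs=0.15)

    def test_missing_seed_rejected(self, toy_panel):
        spec = ps.GaussianSSMSpec(toy_panel)
        with pytest.raises(ValueError, match="seed"):
            ps.fit(spec, ps.MCMCConfig(n_chains=1, n_iter=200, n_burnin=50))


class TestCountFit:
    def test_recovers_detection_and_dispersion(self):
        pan, _ = make_count_panel(n_sites=3, n_times=12, sessions=2,
                                  replicates=3, theta=5.0, p=0.6, seed=23)
        spec = ps.CountSSMSpec(pan)
        res = ps.fit(spec, ps.MCMCConfig(n_chains=1, n_iter=4000, n_burnin=1500,
                                         thin=3, seed=9), save_latents=False)
        for site in pan.site_list:
            assert res.summary[f"p_mean[{site}]"]["mean"] == pytest.approx(0.6, abs=0.15)
        row = res.summary["theta"]
        assert row["ci2.5"] <= 5.0 <= row["ci97.5"] + 1.0
        rho_row = res.summary["rho_prime"]
        assert rho_row["ci2.5"] <= 0.7 <= rho_row["ci97.5"]

    def test_p_one_poisson_limit_matches_gaussian_path(self):
        """With perfect detection and Poisson counts at high abundance the
        count model recovers the same Gompertz parameters as a log-scale
        Gaussian analysis of the counts."""
        proc = ps.ProcessSpec(1.0, -0.4, ps.GICCError(np.full(3, 0.1), 0.7))
        pan, _ = make_count_panel(n_sites=3, n_times=20, sessions=2,
                                  replicates=3, seed=24, poisson_limit=True,
                                  theta=1e6, p=1.0, process=proc)
        spec = ps.CountSSMSpec(pan, poisson_limit=True, fix_p=1.0)
        res = ps.fit(spec, ps.MCMCConfig(n_chains=1, n_iter=3000, n_burnin=1200,
                                         thin=3, seed=10), save_latents=False)
        logy = np.log(pan.site_time_means().pivot(
            index="site", columns="time", values="value").to_numpy() + 0.2)
        cls = [ps.gompertz_cls_fit(logy[i]) for i in range(3)]
        beta_cls = np.mean([f.beta for f in cls])
        row = res.summary["beta"]
        assert row["mean"] == pytest.approx(beta_cls, abs=0.25)
        assert row["ci2.5"] <= -0.4 <= row["ci97.5"]
        assert "theta" not in res.summary.names
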