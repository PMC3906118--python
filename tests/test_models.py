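"""Model specifications, likelihoods and the thinned-NB marginalization."""

import numpy as np
import pytest
from scipy import stats

import popsync as ps
from popsync.models import build_panel_index
from popsync.panel import PanelValidationError

from conftest import make_count_panel


class TestGaussianLoglik:
    def test_closed_form_oracle_two_sites(self, toy_panel):
        """Observation + ICC-transition terms match a longhand sum of
        normal log-densities on the 2-site x 3-time toy panel."""
        spec = ps.GaussianSSMSpec(toy_panel)
        x = np.array([[1.0, 1.1, 0.9], [0.8, 1.0, 1.1]])
        params = dict(alpha=0.3, beta=-0.4, sigma2_c=0.02, sigma2_d=0.01,
                      sigma2_gamma=0.05)
        ll = ps.gaussian_loglik(params, x, spec, gammas=None)
        # oracle: per-record N(y; x, sd^2) plus MVN transition terms
        expected = 0.0
        df = toy_panel.data
        for _, row in df.iterrows():
            i = toy_panel.site_list.index(row.site)
            j = toy_panel.time_grid.index(row.time)
            expected += stats.norm.logpdf(row.value, x[i, j], row.sampling_sd)
        cov = 0.02 * np.ones((2, 2)) + 0.01 * np.eye(2)
        for j in range(2):
            eps = x[:, j + 1] - x[:, j] - 0.3 - (-0.4) * x[:, j]
            expected += stats.multivariate_normal.logpdf(eps, np.zeros(2), cov)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_session_effects_add_their_prior_terms(self, toy_panel):
        spec = ps.GaussianSSMSpec(toy_panel)
        x = np.zeros((2, 3)) + 1.0
        params = dict(alpha=0.0, beta=-0.5, sigma2_c=0.01, sigma2_d=0.01,
                      sigma2_gamma=0.04)
        gammas = np.full(6, 0.1)  # one session per record in the toy panel
        with_g = ps.gaussian_loglik(params, x, spec, gammas=gammas)
        base = ps.gaussian_loglik(params, x, spec, gammas=None)
        # moving the mean by gamma and adding the gamma prior is the difference
        shift = sum(
            stats.norm.logpdf(row.value, 1.0 + 0.1, row.sampling_sd)
            - stats.norm.logpdf(row.value, 1.0, row.sampling_sd)
            for _, row in toy_panel.data.iterrows())
        shift += 6 * stats.norm.logpdf(0.1, 0.0, 0.2)
        assert with_g - base == pytest.approx(shift, rel=1e-10)

    def test_latent_only_site_times_contribute_transitions_only(self, toy_panel):
        """Extending the time grid by an unobserved year changes the
        log-likelihood by exactly one extra transition density."""
        spec3 = ps.GaussianSSMSpec(toy_panel)
        extended = ps.ObservationPanel(toy_panel.data, time_grid=[1, 2, 3, 4])
        spec4 = ps.GaussianSSMSpec(extended)
        x3 = np.array([[1.0, 1.1, 0.9], [0.8, 1.0, 1.1]])
        x4 = np.column_stack([x3, [1.0, 1.0]])
        params = dict(alpha=0.2, beta=-0.3, sigma2_c=0.02, sigma2_d=0.01,
                      sigma2_gamma=0.05)
        cov = 0.02 * np.ones((2, 2)) + 0.01 * np.eye(2)
        eps = x4[:, 3] - x4[:, 2] - 0.2 - (-0.3) * x4[:, 2]
        extra = stats.multivariate_normal.logpdf(eps, np.zeros(2), cov)
        assert ps.gaussian_loglik(params, x4, spec4) == pytest.approx(
            ps.gaussian_loglik(params, x3, spec3) + extra, rel=1e-10)

    def test_zero_variance_rejected(self, toy_panel):
        spec = ps.GaussianSSMSpec(toy_panel)
        x = np.ones((2, 3))
        with pytest.raises(ValueError):
            ps.gaussian_loglik(dict(alpha=0, beta=-0.5, sigma2_c=0.01,
                                    sigma2_d=0.0, sigma2_gamma=0.01), x, spec)

    def test_requires_assigned_sampling_sd(self, toy_panel):
        df = toy_panel.data.assign(sampling_sd=np.nan)
        with pytest.raises(PanelValidationError, match="sampling_sd"):
            ps.GaussianSSMSpec(ps.ObservationPanel(df))


class TestThinnedNB:
    def test_no_thinning_equals_plain_nb(self):
        c, lam, theta = np.arange(15), 3.0, 2.5
        ours = ps.thinned_nb_logpmf(c, lam, theta, 1.0)
        scipy_ref = stats.nbinom.logpmf(c, theta, theta / (theta + lam))
        np.testing.assert_allclose(ours, scipy_ref, atol=1e-10)

    @pytest.mark.parametrize("theta", [0.7, 5.11, 50.0])
    @pytest.mark.parametrize("p", [0.3, 0.7, 1.0])
    def test_closed_form_equals_latent_sum(self, theta, p):
        """Marginalizing availability N analytically equals the explicit
        truncated summation over N for all small cases (lambda <= 5, c <= 20)."""
        for lam in [0.5, 2.0, 5.0]:
            for c in range(0, 21):
                closed = ps.thinned_nb_logpmf(c, lam, theta, p)
                brute = ps.thinned_nb_logpmf_bruteforce(c, lam, theta, p)
                assert closed == pytest.approx(brute, abs=1e-8), (lam, c)

    def test_poisson_limit_matches_poisson_pmf(self):
        flag = ps.thinned_nb_logpmf(3, 2.0, np.inf, 1.0, poisson_limit=True)
        assert flag == pytest.approx(stats.poisson.logpmf(3, 2.0), abs=1e-12)
        big_theta = ps.thinned_nb_logpmf(3, 2.0, 1e8, 1.0)
        assert big_theta == pytest.approx(stats.poisson.logpmf(3, 2.0), abs=1e-6)


class TestCountLoglik:
    def test_finite_on_randomized_panels(self):
        for seed in range(5):
            pan, _ = make_count_panel(seed=seed, n_times=6)
            spec = ps.CountSSMSpec(pan)
            rng = np.random.default_rng(seed)
            x = rng.normal(1.0, 0.5, size=(pan.n_sites, pan.n_times))
            gam = rng.normal(0, 0.1, size=spec.index.sess_site.size)
            p_st = rng.uniform(0.2, 0.9, size=spec.index.st_site.size)
            ll = ps.count_loglik(
                dict(alpha=0.5, beta=-0.4, rho_prime=0.6, theta=4.0, b=0.1,
                     sigma2_gamma=0.02, sigma2_site=np.full(pan.n_sites, 0.1)),
                x, spec, gammas=gam, p_sitetime=p_st)
            assert np.isfinite(ll)

    def test_observation_term_matches_thinned_nb(self):
        pan, _ = make_count_panel(seed=3, n_times=5, sigma2_gamma=0.0)
        spec = ps.CountSSMSpec(pan)
        x = np.full((pan.n_sites, pan.n_times), 1.2)
        params = dict(alpha=0.5, beta=-0.4, rho_prime=0.5, theta=5.0, b=0.0,
                      sigma2_gamma=0.01, sigma2_site=np.full(pan.n_sites, 0.1))
        ll = ps.count_loglik(params, x, spec,
                             p_sitetime=np.full(spec.index.st_site.size, 0.6))
        obs = ps.thinned_nb_logpmf(pan.data.value.to_numpy(), np.exp(1.2),
                                   5.0, 0.6).sum()
        trans = ps.transition_loglik(x, 0.5, -0.4, np.full(pan.n_sites, 0.1), 0.5)
        assert ll == pytest.approx(obs + trans, rel=1e-10)

    def test_count_model_requires_log_distance(self, toy_panel):
        df = toy_panel.data.assign(kind="count", value=1.0, sampling_sd=np.nan,
                                   log_distance=np.nan)
        with pytest.raises(PanelValidationError, match="log_distance"):
            ps.CountSSMSpec(ps.ObservationPanel(df))

    def test_few_counts_per_site_time_warns(self):
        pan, _ = make_count_panel(seed=4, n_times=5, sessions=1, replicates=1)
        with pytest.warns(UserWarning, match="< 2 counts"):
            ps.CountSSMSpec(pan)


class TestTransitionLoglik:
    def test_compound_symmetry_matches_mvn_oracle(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(4, 8))
        s2 = np.array([0.2, 0.5, 0.3, 0.4])
        rho = 0.65
        ll = ps.transition_loglik(x, 0.1, -0.3, s2, rho)
        sd = np.sqrt(s2)
        cov = rho * np.outer(sd, sd)
        cov[np.diag_indices(4)] = s2
        expected = sum(
            stats.multivariate_normal.logpdf(
                x[:, j + 1] - x[:, j] - 0.1 - (-0.3) * x[:, j], np.zeros(4), cov)
            for j in range(7))
        assert ll == pytest.approx(expected, rel=1e-10)


class TestDeriveSynchrony:
    def test_equal_components_give_half(self):
        rho = ps.derive_synchrony({"sigma2_c": np.array([0.3, 0.1]),
                                   "sigma2_d": np.array([0.3, 0.1])})
        np.testing.assert_allclose(rho, 0.5)

    def test_no_unshared_variance_gives_one(self):
        rho = ps.derive_synchrony({"sigma2_c": np.array([0.3]),
                                   "sigma2_d": np.array([0.0])})
        np.testing.assert_allclose(rho, 1.0)

    def test_gicc_passthrough(self):
        draws = {"rho_prime": np.array([0.2, 0.9])}
        np.testing.assert_allclose(ps.derive_synchrony(draws), [0.2, 0.9])

    def test_zero_total_draws_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluding"):
            rho = ps.derive_synchrony({"sigma2_c": np.array([0.0, 0.2]),
                                       "sigma2_d": np.array([0.0, 0.2])})
        assert rho.size == 1


def test_priors_match_scipy_densities():
    priors = ps.PriorSet()
    assert priors.logpdf_invgamma(0.3) == pytest.approx(
        stats.invgamma.logpdf(0.3, 0.001, scale=0.001), rel=1e-10)
    assert priors.logpdf_normal(1.7) == pytest.approx(
        stats.norm.logpdf(1.7, 0, np.sqrt(1000)), rel=1e-10)
    assert priors.logpdf_exponential(2.0) == pytest.approx(
        stats.expon.logpdf(2.0), rel=1e-10)
    assert priors.logpdf_uniform01(0.5) == 0.0
    assert priors.logpdf_uniform01(1.5) == -np.inf


def test_panel_index_round_trips_record_order(toy_panel):
    idx = build_panel_index(toy_panel)
    assert idx.rec_value.size == 6
    assert idx.sess_site.size == 6  # one session per (site, time) here
    assert idx.n_sites == 2 and idx.n_times == 3
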