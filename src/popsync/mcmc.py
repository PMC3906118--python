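"""Posterior sampling for the two state-space models.

Gaussian model
    The model is linear-Gaussian given the five hyperparameters
    (alpha, beta, sigma2_c, sigma2_d, sigma2_gamma): latent states, session
    effects and the shared year effects are marginalized *exactly* by a
    Kalman filter over the site-vector state, and an adaptive random-walk
    Metropolis chain runs on the hyperparameters alone (variances on the
    log scale).  Latent-state draws are recovered afterwards by
    forward-filter backward-sampling (FFBS).  Marginalization sidesteps the
    slow mixing of single-site Gibbs updates at short series lengths.

Count model
    The thinned-NB observation density is not conjugate, so latent states
    and session effects stay explicit and everything is updated by
    Metropolis-within-Gibbs with Robbins-Monro scale adaptation during
    burn-in.

The contract is distributional correctness (parameter recovery and
prior-predictive checks), not kernel identity with any particular sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import linalg

from .estimators import gompertz_cls_fit
from .models import (
    CountSSMSpec,
    GaussianSSMSpec,
    PriorSet,
    derive_synchrony,
    thinned_nb_logpmf,
    transition_loglik,
)
from .panel import PosteriorSummary

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class MCMCConfig:
    """Chain management settings.

    The default is a desk-scale configuration; :meth:`published_scale` returns
    the heavy setting (3 chains of 1.2M, 100k burn-in, thin 100) used for
    the published real-data fits.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int | None = None
    max_latent_draws: int = 500
    init_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @classmethod
    def published_scale(cls, seed: int | None = None) -> "MCMCConfig":
        return cls(n_chains=3, n_iter=1_200_000, n_burnin=100_000, thin=100, seed=seed)


# --------------------------------------------------------------------------
# diagnostics and summaries
# --------------------------------------------------------------------------


def gelman_rubin(chains) -> float | dict[str, float]:
    """Potential scale reduction factor (between/within-chain variance form).

    ``chains`` is an (n_chains, n_draws) array for one parameter, or a dict
    of such arrays.  The variance ratio is floored at 1 so that identical
    chains return exactly 1.0 and R-hat >= 1 always holds.
    """
    if isinstance(chains, dict):
        return {name: gelman_rubin(c) for name, c in chains.items()}
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = arr.shape
    if n < 10:
        raise ValueError("need >= 10 retained draws per chain")
    w = arr.var(axis=1, ddof=1).mean()
    b = n * arr.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(max(var_plus / w, 1.0)))


def summarize(draws: dict[str, np.ndarray]) -> PosteriorSummary:
    """Posterior mean, SD, equal-tailed 95% CI (and R-hat when >= 2 chains)
    per parameter.  Each entry of ``draws`` is (n_chains, n_kept)."""
    rows = []
    for name, arr in draws.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        flat = arr.ravel()
        rhat = np.nan
        if arr.shape[0] >= 2 and arr.shape[1] >= 10:
            rhat = gelman_rubin(arr)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows.append((name, float(flat.mean()),
                     float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                     float(lo), float(hi), rhat))
    table = pd.DataFrame(rows, columns=["name", "mean", "sd", "ci2.5", "ci97.5", "rhat"])
    return PosteriorSummary(table, draws=dict(draws))


@dataclass
class FitResult:
    """Posterior draws plus summaries from a state-space fit."""

    summary: PosteriorSummary
    draws: dict[str, np.ndarray]            # name -> (n_chains, n_kept)
    site_list: list[str]
    time_grid: list[int]
    x_draws: np.ndarray | None = None       # (n_chains, n_saved, n_sites, n_times)
    x_alpha: np.ndarray | None = field(default=None, repr=False)
    x_beta: np.ndarray | None = field(default=None, repr=False)

    def rho_draws(self) -> np.ndarray:
        flat = {k: v.ravel() for k, v in self.draws.items()}
        return derive_synchrony(flat)

    def latent_means(self) -> np.ndarray:
        if self.x_draws is None:
            raise ValueError("fit was run without latent draws")
        return self.x_draws.mean(axis=(0, 1))

    def residual_means(self) -> np.ndarray:
        """Posterior-mean process residuals eps_ij = x_{j+1} - x_j - a - b x_j,
        an (n_sites, n_times - 1) matrix; feed to residual_corr_matrix."""
        if self.x_draws is None:
            raise ValueError("fit was run without latent draws")
        x = self.x_draws.reshape(-1, *self.x_draws.shape[2:])
        a = self.x_alpha.reshape(-1)[:, None, None]
        b = self.x_beta.reshape(-1)[:, None, None]
        eps = x[:, :, 1:] - x[:, :, :-1] - a - b * x[:, :, :-1]
        return eps.mean(axis=0)


# --------------------------------------------------------------------------
# Gaussian model: Kalman-marginalized adaptive Metropolis + FFBS
# --------------------------------------------------------------------------


@numba.njit(cache=False)
def _kalman_ll(ybw: np.ndarray, wgrid: np.ndarray, phi: float, drift: float,
               qc: float, qd: float, m0: np.ndarray, c0: float) -> float:
    """Marginal log-likelihood of collapsed site-time observations.

    ``ybw[i, t]`` is the precision-weighted mean of the session means at
    (site i, time t) and ``wgrid[i, t]`` its total precision (0 where the
    site-time is latent-only).  Sequential scalar updates are exact because
    the collapsed observation covariance is diagonal.
    """
    ns, nt = ybw.shape
    m = m0.copy()
    p = np.eye(ns) * c0
    ll = 0.0
    for t in range(nt):
        for i in range(ns):
            w = wgrid[i, t]
            if w > 0.0:
                s = p[i, i] + 1.0 / w
                nu = ybw[i, t] - m[i]
                ll += -0.5 * (_LOG_2PI + np.log(s) + nu * nu / s)
                kvec = p[:, i].copy() / s
                prow = p[i, :].copy()
                for a in range(ns):
                    m[a] += kvec[a] * nu
                    for b2 in range(ns):
                        p[a, b2] -= kvec[a] * prow[b2]
        if t < nt - 1:
            for a in range(ns):
                m[a] = drift + phi * m[a]
            for a in range(ns):
                for b2 in range(ns):
                    p[a, b2] = phi * phi * p[a, b2] + qc
                p[a, a] += qd
    return ll


class _GaussianKalman:
    """Collapsed observation structures and the marginal-likelihood filter.

    Replicates within a session are reduced to the session mean (their
    residual terms depend only on the *assigned* sampling variances, hence
    are constant over the chain and dropped); sessions within a site-time
    are reduced to a precision-weighted mean plus an analytic remainder
    that carries the sigma2_gamma dependence.
    """

    def __init__(self, spec: GaussianSSMSpec):
        idx = spec.index
        self.n_sites = idx.n_sites
        self.n_times = idx.n_times
        n_sess = idx.sess_site.size
        # session means and within-session variances of the mean (v / k)
        sess_y = np.zeros(n_sess)
        sess_vk = np.zeros(n_sess)
        for f in range(n_sess):
            mask = idx.rec_session == f
            sess_y[f] = idx.rec_value[mask].mean()
            sess_vk[f] = idx.rec_var[mask].mean() / mask.sum()
        self.sess_y = sess_y
        self.sess_vk = sess_vk
        self.sess_flat = idx.sess_site * self.n_times + idx.sess_time
        self.n_flat = self.n_sites * self.n_times
        # vague proper initial prior centered on per-site observed means
        m0 = np.zeros(self.n_sites)
        if idx.rec_value.size:
            overall = idx.rec_value.mean()
            for i in range(self.n_sites):
                vals = idx.rec_value[idx.rec_site == i]
                m0[i] = vals.mean() if vals.size else overall
        self.m0 = m0
        self.C0 = 25.0

    def _collapse(self, s2g: float):
        """Precision-weighted site-time means, their precisions, and the
        x-independent remainder of the session-level Gaussian likelihood."""
        u = s2g + self.sess_vk
        inv_u = 1.0 / u
        w = np.bincount(self.sess_flat, weights=inv_u, minlength=self.n_flat)
        ysum = np.bincount(self.sess_flat, weights=self.sess_y * inv_u,
                           minlength=self.n_flat)
        observed = w > 0
        ybw = np.zeros(self.n_flat)
        ybw[observed] = ysum[observed] / w[observed]
        rem = -0.5 * (np.sum(np.log(2.0 * np.pi * u))
                      + np.sum(np.log(w[observed] / (2.0 * np.pi)))
                      + np.sum(self.sess_y ** 2 * inv_u)
                      - np.sum(w[observed] * ybw[observed] ** 2))
        shape = (self.n_sites, self.n_times)
        return ybw.reshape(shape), w.reshape(shape), float(rem)

    def _trans(self, alpha, beta, s2c, s2d):
        n = self.n_sites
        q = s2c * np.ones((n, n)) + s2d * np.eye(n)
        return 1.0 + beta, alpha, q

    def loglik(self, alpha, beta, s2c, s2d, s2g) -> float:
        """Exact marginal log-likelihood (up to a constant that depends only
        on the assigned sampling variances)."""
        ybw, wgrid, rem = self._collapse(s2g)
        ll = _kalman_ll(ybw, wgrid, 1.0 + beta, alpha, s2c, s2d, self.m0, self.C0)
        return float(ll + rem)

    def _filter_moments(self, alpha, beta, s2c, s2d, s2g):
        """Python-side filter keeping per-time filtered (m, P) for FFBS."""
        n = self.n_sites
        phi, drift, q = self._trans(alpha, beta, s2c, s2d)
        ybw, wgrid, _ = self._collapse(s2g)
        m = self.m0.copy()
        p = self.C0 * np.eye(n)
        moments = []
        for t in range(self.n_times):
            for i in range(n):
                w = wgrid[i, t]
                if w > 0:
                    s = p[i, i] + 1.0 / w
                    nu = ybw[i, t] - m[i]
                    k = p[:, i] / s
                    m = m + k * nu
                    p = p - np.outer(k, p[i, :])
                    p = 0.5 * (p + p.T)
            moments.append((m.copy(), p.copy()))
            if t < self.n_times - 1:
                m = drift + phi * m
                p = phi * phi * p + q
        return moments

    def ffbs(self, alpha, beta, s2c, s2d, s2g,
             rng: np.random.Generator) -> np.ndarray:
        """One joint posterior draw of the latent site x time grid."""
        moments = self._filter_moments(alpha, beta, s2c, s2d, s2g)
        n, t = self.n_sites, self.n_times
        phi, drift, q = self._trans(alpha, beta, s2c, s2d)
        x = np.empty((n, t))
        m_f, p_f = moments[t - 1]
        x[:, t - 1] = rng.multivariate_normal(
            m_f, p_f + 1e-12 * np.eye(n), method="cholesky")
        for j in range(t - 2, -1, -1):
            m_f, p_f = moments[j]
            a_next = drift + phi * m_f
            r_next = phi * phi * p_f + q
            g = phi * linalg.solve(r_next, p_f, assume_a="pos").T
            mean = m_f + g @ (x[:, j + 1] - a_next)
            cov = p_f - g @ r_next @ g.T
            cov = 0.5 * (cov + cov.T) + 1e-12 * np.eye(n)
            x[:, j] = rng.multivariate_normal(mean, cov, method="cholesky")
        return x


def _gaussian_logpost(eta: np.ndarray, kal: _GaussianKalman,
                      priors: PriorSet) -> float:
    alpha, beta, zc, zd, zg = eta
    if max(abs(zc), abs(zd), abs(zg)) > 40:
        return -np.inf
    s2c, s2d, s2g = np.exp([zc, zd, zg])
    lp = (priors.logpdf_normal(alpha) + priors.logpdf_normal(beta)
          + priors.logpdf_invgamma(s2c) + zc
          + priors.logpdf_invgamma(s2d) + zd
          + priors.logpdf_invgamma(s2g) + zg)
    if not np.isfinite(lp):
        return -np.inf
    return lp + kal.loglik(alpha, beta, s2c, s2d, s2g)


def _gaussian_init(spec: GaussianSSMSpec, rng: np.random.Generator) -> np.ndarray:
    """Initial values: Gompertz CLS on site-time means, moment-based variance
    split, jittered."""
    idx = spec.index
    alpha0, beta0 = 0.0, -0.5
    s2c0, s2d0 = 0.05, 0.05
    if idx.rec_value.size:
        grid = np.full((idx.n_sites, idx.n_times), np.nan)
        for i in range(idx.n_sites):
            for j in range(idx.n_times):
                vals = idx.rec_value[(idx.rec_site == i) & (idx.rec_time == j)]
                if vals.size:
                    grid[i, j] = vals.mean()
        resid = []
        ab = []
        for i in range(idx.n_sites):
            try:
                f = gompertz_cls_fit(grid[i])
                ab.append((f.alpha, f.beta))
                resid.append(f.residuals)
            except ValueError:
                pass
        if ab:
            alpha0 = float(np.mean([a for a, _ in ab]))
            beta0 = float(np.clip(np.mean([b for _, b in ab]), -1.9, -0.02))
            r = np.array(resid)
            tot = np.nanvar(r)
            if np.isfinite(tot) and tot > 0:
                s2c0 = max(tot / 2, 1e-3)
                s2d0 = max(tot / 2, 1e-3)
    eta = np.array([alpha0, beta0, np.log(s2c0), np.log(s2d0), np.log(0.01)])
    jitter = np.array([0.1, 0.05, 0.3, 0.3, 0.3])
    return eta + jitter * rng.standard_normal(5)


def _adaptive_metropolis(logpost, init_fn, n_iter, n_burnin, thin,
                         rng: np.random.Generator, d: int,
                         init_scales: np.ndarray, retries: int):
    """Haario-style adaptive random-walk Metropolis; adaptation frozen after
    burn-in.  Returns (kept draws, acceptance rate)."""
    for _ in range(retries):
        eta = init_fn(rng)
        lp = logpost(eta)
        if np.isfinite(lp):
            break
    else:
        raise RuntimeError("could not find finite log-posterior initial values")
    cov = np.diag(init_scales ** 2)
    chol = np.linalg.cholesky(cov)
    history = np.empty((n_iter, d))
    kept = []
    accepted = 0
    sd = 2.38 ** 2 / d
    for it in range(n_iter):
        prop = eta + chol @ rng.standard_normal(d)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            eta, lp = prop, lp_prop
            accepted += 1
        history[it] = eta
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            kept.append(eta.copy())
        if it < n_burnin and it >= 200 and it % 50 == 0:
            emp = np.cov(history[max(0, it - 2000):it + 1].T)
            cov = sd * emp + 1e-9 * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass
    return np.array(kept), accepted / n_iter


def _fit_gaussian(spec: GaussianSSMSpec, config: MCMCConfig,
                  save_latents: bool) -> FitResult:
    kal = _GaussianKalman(spec)
    if config.seed is None:
        raise ValueError("MCMCConfig.seed is required")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    for cs in seeds:
        rng = np.random.default_rng(cs)
        kept, _ = _adaptive_metropolis(
            lambda e: _gaussian_logpost(e, kal, spec.priors),
            lambda r: _gaussian_init(spec, r),
            config.n_iter, config.n_burnin, config.thin, rng, d=5,
            init_scales=np.array([0.1, 0.05, 0.5, 0.5, 0.5]),
            retries=config.init_retries)
        chains.append(kept)
    kept = np.array(chains)  # (n_chains, n_kept, 5)
    draws = {
        "alpha": kept[:, :, 0],
        "beta": kept[:, :, 1],
        "sigma2_c": np.exp(kept[:, :, 2]),
        "sigma2_d": np.exp(kept[:, :, 3]),
        "sigma2_gamma": np.exp(kept[:, :, 4]),
    }
    draws["rho"] = draws["sigma2_c"] / (draws["sigma2_c"] + draws["sigma2_d"])
    x_draws = x_alpha = x_beta = None
    if save_latents:
        n_kept = kept.shape[1]
        n_save = min(config.max_latent_draws, n_kept)
        pick = np.linspace(0, n_kept - 1, n_save).astype(int)
        x_draws = np.empty((config.n_chains, n_save, kal.n_sites, kal.n_times))
        x_alpha = np.empty((config.n_chains, n_save))
        x_beta = np.empty((config.n_chains, n_save))
        for c, cs in enumerate(seeds):
            rng = np.random.default_rng(cs.spawn(1)[0])
            for s, k in enumerate(pick):
                a, b, zc, zd, zg = kept[c, k]
                x_draws[c, s] = kal.ffbs(a, b, *np.exp([zc, zd, zg]), rng)
                x_alpha[c, s] = a
                x_beta[c, s] = b
    return FitResult(summary=summarize(draws), draws=draws,
                     site_list=spec.panel.site_list, time_grid=spec.panel.time_grid,
                     x_draws=x_draws, x_alpha=x_alpha, x_beta=x_beta)


# --------------------------------------------------------------------------
# count model: Metropolis-within-Gibbs
# --------------------------------------------------------------------------


class _CountState:
    """Mutable chain state for the count sampler."""

    def __init__(self, spec: CountSSMSpec, rng: np.random.Generator):
        idx = spec.index
        self.idx = idx
        self.poisson = spec.poisson_limit
        # latent grid init: log(mean count / 0.5 + 0.2) where observed
        grid = np.full((idx.n_sites, idx.n_times), np.nan)
        for st, (i, j) in enumerate(zip(idx.st_site, idx.st_time)):
            c_mean = idx.rec_value[idx.rec_sitetime == st].mean()
            grid[i, j] = np.log(c_mean / 0.5 + 0.2)
        site_means = np.nanmean(np.where(np.isfinite(grid), grid, np.nan), axis=1)
        site_means = np.where(np.isfinite(site_means), site_means, 0.0)
        for i in range(idx.n_sites):
            grid[i, ~np.isfinite(grid[i])] = site_means[i]
        self.x = grid + 0.05 * rng.standard_normal(grid.shape)
        self.gam = np.zeros(idx.sess_site.size)
        if spec.fix_p is not None:
            if not 0.0 < spec.fix_p <= 1.0:
                raise ValueError("fix_p must lie in (0, 1]")
            self.fixed_p = True
            z = 37.0 if spec.fix_p == 1.0 else float(np.log(spec.fix_p / (1 - spec.fix_p)))
            self.logit_p = np.full(idx.st_site.size, z)
        else:
            self.fixed_p = False
            self.logit_p = np.zeros(idx.st_site.size) + 0.2 * rng.standard_normal(idx.st_site.size)
        self.alpha = 0.0 + 0.1 * rng.standard_normal()
        self.beta = -0.5 + 0.1 * rng.standard_normal()
        self.b = 0.0 + 0.05 * rng.standard_normal()
        self.log_theta = np.log(1.0) + 0.2 * rng.standard_normal()
        self.logit_rho = 0.0 + 0.2 * rng.standard_normal()
        self.log_s2g = np.log(0.05) + 0.2 * rng.standard_normal()
        self.log_s2site = np.log(0.1) + 0.2 * rng.standard_normal(idx.n_sites)
        # per-column record lists for latent updates
        self.cols = [np.flatnonzero(idx.rec_time == j) for j in range(idx.n_times)]

    # -- pieces of the log target -----------------------------------------

    def obs_loglik(self, rec: np.ndarray | slice = slice(None),
                   x=None, gam=None, b=None, log_theta=None, logit_p=None):
        idx = self.idx
        x = self.x if x is None else x
        gam = self.gam if gam is None else gam
        b = self.b if b is None else b
        log_theta = self.log_theta if log_theta is None else log_theta
        logit_p = self.logit_p if logit_p is None else logit_p
        rs, rt = idx.rec_site[rec], idx.rec_time[rec]
        eta = x[rs, rt] + b * idx.rec_logdist[rec] + gam[idx.rec_session[rec]]
        p = 1.0 / (1.0 + np.exp(-logit_p[idx.rec_sitetime[rec]]))
        return thinned_nb_logpmf(idx.rec_value[rec], np.exp(eta),
                                 np.exp(log_theta), p, poisson_limit=self.poisson)

    def trans_loglik(self, x=None, alpha=None, beta=None,
                     log_s2site=None, logit_rho=None):
        x = self.x if x is None else x
        alpha = self.alpha if alpha is None else alpha
        beta = self.beta if beta is None else beta
        s2 = np.exp(self.log_s2site if log_s2site is None else log_s2site)
        rho = _expit(self.logit_rho if logit_rho is None else logit_rho)
        return transition_loglik(x, alpha, beta, s2, rho)

    def gam_prior(self, gam=None, log_s2g=None):
        gam = self.gam if gam is None else gam
        s2g = np.exp(self.log_s2g if log_s2g is None else log_s2g)
        return float(np.sum(-0.5 * (_LOG_2PI + np.log(s2g) + gam ** 2 / s2g)))


def _expit(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z)))


class _ScaleAdapter:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, scale: float, target: float = 0.35):
        self.scale = scale
        self.target = target
        self.accepts = 0.0
        self.tries = 0
        self.rounds = 1

    def record(self, accepted: float, tries: int = 1) -> None:
        self.accepts += accepted
        self.tries += tries

    def maybe_adapt(self) -> None:
        if self.tries >= 50:
            rate = self.accepts / self.tries
            self.scale *= np.exp((rate - self.target) / np.sqrt(self.rounds))
            self.scale = float(np.clip(self.scale, 1e-4, 10.0))
            self.rounds += 1
            self.accepts = 0.0
            self.tries = 0


def _fit_count(spec: CountSSMSpec, config: MCMCConfig,
               save_latents: bool) -> FitResult:
    if config.seed is None:
        raise ValueError("MCMCConfig.seed is required")
    priors = spec.priors
    idx = spec.index
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_kept = (config.n_iter - config.n_burnin + config.thin - 1) // config.thin
    names = ["alpha", "beta", "rho_prime", "sigma2_gamma", "b"]
    if not spec.poisson_limit:
        names.append("theta")
    names += [f"sigma2_site[{s}]" for s in spec.panel.site_list]
    if spec.fix_p is None:
        names += [f"p_mean[{s}]" for s in spec.panel.site_list]
    all_draws = {n: np.empty((config.n_chains, n_kept)) for n in names}
    n_save = min(config.max_latent_draws, n_kept)
    pick = set(np.linspace(0, n_kept - 1, n_save).astype(int))
    x_draws = np.empty((config.n_chains, n_save, idx.n_sites, idx.n_times))
    x_alpha = np.empty((config.n_chains, n_save))
    x_beta = np.empty((config.n_chains, n_save))

    for c, cs in enumerate(seeds):
        rng = np.random.default_rng(cs)
        st = None
        for _ in range(config.init_retries):
            cand = _CountState(spec, rng)
            if np.isfinite(np.sum(cand.obs_loglik())) and np.isfinite(cand.trans_loglik()):
                st = cand
                break
        if st is None:
            raise RuntimeError("could not find finite log-posterior initial values")

        ad = {k: _ScaleAdapter(s) for k, s in
              [("x", 0.2), ("gam", 0.2), ("p", 0.5),
               ("lvl", 0.3), ("lvlp", 0.3),
               ("s2site", 0.4), ("rho", 0.5), ("s2g", 0.4),
               ("theta", 0.3), ("b", 0.05)]}
        kept_i = 0
        saved_i = 0
        for it in range(config.n_iter):
            _count_sweep(st, priors, ad, rng)
            if it < config.n_burnin:
                for a in ad.values():
                    a.maybe_adapt()
            elif (it - config.n_burnin) % config.thin == 0 and kept_i < n_kept:
                all_draws["alpha"][c, kept_i] = st.alpha
                all_draws["beta"][c, kept_i] = st.beta
                all_draws["rho_prime"][c, kept_i] = _expit(st.logit_rho)
                all_draws["sigma2_gamma"][c, kept_i] = np.exp(st.log_s2g)
                if not spec.poisson_limit:
                    all_draws["theta"][c, kept_i] = np.exp(st.log_theta)
                all_draws["b"][c, kept_i] = st.b
                p_now = _expit(st.logit_p)
                for i, sname in enumerate(spec.panel.site_list):
                    all_draws[f"sigma2_site[{sname}]"][c, kept_i] = np.exp(st.log_s2site[i])
                    if spec.fix_p is None:
                        mask = idx.st_site == i
                        all_draws[f"p_mean[{sname}]"][c, kept_i] = (
                            p_now[mask].mean() if mask.any() else np.nan)
                if kept_i in pick and saved_i < n_save:
                    x_draws[c, saved_i] = st.x
                    x_alpha[c, saved_i] = st.alpha
                    x_beta[c, saved_i] = st.beta
                    saved_i += 1
                kept_i += 1

    result_draws = dict(all_draws)
    summary = summarize(result_draws)
    return FitResult(summary=summary, draws=result_draws,
                     site_list=spec.panel.site_list, time_grid=spec.panel.time_grid,
                     x_draws=x_draws if save_latents else None,
                     x_alpha=x_alpha if save_latents else None,
                     x_beta=x_beta if save_latents else None)


def _draw_alpha_beta(st: _CountState, priors: PriorSet, rng) -> None:
    """Gibbs draw of (alpha, beta) from their bivariate-normal conditional."""
    x = st.x
    n = x.shape[0]
    s2 = np.exp(st.log_s2site)
    rho = float(_expit(st.logit_rho))
    # Sigma^-1 for the compound-symmetric error covariance
    dinv = 1.0 / np.sqrt(s2)
    one_m = 1.0 - rho
    denom = one_m + n * rho
    cinv = (np.eye(n) - (rho / denom) * np.ones((n, n))) / one_m
    sig_inv = dinv[:, None] * cinv * dinv[None, :]
    lag = x[:, :-1]
    d = x[:, 1:] - lag
    # precision and mean of (alpha, beta): sum_j Z_j' S^-1 Z_j etc.
    si_one = sig_inv.sum(axis=0)             # 1' S^-1  (n,)
    a11 = sig_inv.sum() * lag.shape[1]
    a12 = float(si_one @ lag.sum(axis=1))
    a22 = float(np.einsum("it,ij,jt->", lag, sig_inv, lag))
    b1 = float(si_one @ d.sum(axis=1))
    b2 = float(np.einsum("it,ij,jt->", lag, sig_inv, d))
    prec = np.array([[a11, a12], [a12, a22]]) + np.eye(2) / priors.V0
    mean = np.linalg.solve(prec, np.array([b1, b2]))
    cov = np.linalg.inv(prec)
    draw = rng.multivariate_normal(mean, cov, method="cholesky")
    st.alpha, st.beta = float(draw[0]), float(draw[1])


def _count_sweep(st: _CountState, priors: PriorSet, ad: dict, rng) -> None:
    idx = st.idx
    # latent columns, joint across sites per time
    for j in range(idx.n_times):
        rec = st.cols[j]
        prop = st.x.copy()
        prop[:, j] = st.x[:, j] + ad["x"].scale * rng.standard_normal(idx.n_sites)
        cur = np.sum(st.obs_loglik(rec)) + st.trans_loglik()
        new = np.sum(st.obs_loglik(rec, x=prop)) + st.trans_loglik(x=prop)
        acc = np.log(rng.random()) < new - cur
        if acc:
            st.x = prop
        ad["x"].record(acc)
    # session effects: independent given the rest -> vectorized proposal
    if st.gam.size:
        prop_g = st.gam + ad["gam"].scale * rng.standard_normal(st.gam.size)
        s2g = np.exp(st.log_s2g)
        d_obs = st.obs_loglik(gam=prop_g) - st.obs_loglik()
        d_per_sess = np.bincount(idx.rec_session, weights=d_obs, minlength=st.gam.size)
        d_prior = -0.5 * (prop_g ** 2 - st.gam ** 2) / s2g
        acc = np.log(rng.random(st.gam.size)) < d_per_sess + d_prior
        st.gam = np.where(acc, prop_g, st.gam)
        ad["gam"].record(acc.mean())
    # detection probabilities: independent across site-times
    if not st.fixed_p:
        prop_p = st.logit_p + ad["p"].scale * rng.standard_normal(st.logit_p.size)
        d_obs = st.obs_loglik(logit_p=prop_p) - st.obs_loglik()
        d_per_st = np.bincount(idx.rec_sitetime, weights=d_obs, minlength=st.logit_p.size)
        d_jac = (np.log(_expit(prop_p)) + np.log(_expit(-prop_p))
                 - np.log(_expit(st.logit_p)) - np.log(_expit(-st.logit_p)))
        acc = np.log(rng.random(st.logit_p.size)) < d_per_st + d_jac
        st.logit_p = np.where(acc, prop_p, st.logit_p)
        ad["p"].record(acc.mean())
    # joint level shift x -> x + delta, alpha -> alpha - beta*delta: leaves all
    # transition residuals unchanged, so only the observation terms and the
    # alpha prior move -- traverses the abundance-detection ridge
    delta = ad["lvl"].scale * rng.standard_normal()
    pa = st.alpha - st.beta * delta
    cur = np.sum(st.obs_loglik()) + priors.logpdf_normal(st.alpha)
    new = np.sum(st.obs_loglik(x=st.x + delta)) + priors.logpdf_normal(pa)
    acc = np.log(rng.random()) < new - cur
    if acc:
        st.x = st.x + delta
        st.alpha = pa
    ad["lvl"].record(acc)
    # same level shift with detection odds scaled down by e^delta, keeping the
    # expected count roughly constant (symmetric move in (x, alpha, logit p))
    if not st.fixed_p:
        _level_p_move(st, priors, ad, rng)
    # (alpha, beta): exact conjugate bivariate-normal conditional given the
    # latents (GLS regression of increments on lagged states with known
    # compound-symmetric error covariance)
    _draw_alpha_beta(st, priors, rng)
    # per-site process variances
    for i in range(idx.n_sites):
        prop_z = st.log_s2site.copy()
        prop_z[i] += ad["s2site"].scale * rng.standard_normal()
        cur = st.trans_loglik() + priors.logpdf_invgamma(np.exp(st.log_s2site[i])) + st.log_s2site[i]
        new = st.trans_loglik(log_s2site=prop_z) + priors.logpdf_invgamma(np.exp(prop_z[i])) + prop_z[i]
        acc = np.log(rng.random()) < new - cur
        if acc:
            st.log_s2site = prop_z
        ad["s2site"].record(acc)
    # shared fraction rho'
    pz = st.logit_rho + ad["rho"].scale * rng.standard_normal()
    jac = lambda z: np.log(_expit(z)) + np.log(_expit(-z))  # noqa: E731
    cur = st.trans_loglik() + jac(st.logit_rho)
    new = st.trans_loglik(logit_rho=pz) + jac(pz)
    acc = np.log(rng.random()) < new - cur
    if acc:
        st.logit_rho = pz
    ad["rho"].record(acc)
    # session-effect variance
    pz = st.log_s2g + ad["s2g"].scale * rng.standard_normal()
    cur = st.gam_prior() + priors.logpdf_invgamma(np.exp(st.log_s2g)) + st.log_s2g
    new = st.gam_prior(log_s2g=pz) + priors.logpdf_invgamma(np.exp(pz)) + pz
    acc = np.log(rng.random()) < new - cur
    if acc:
        st.log_s2g = pz
    ad["s2g"].record(acc)
    # NB dispersion
    if not st.poisson:
        pz = st.log_theta + ad["theta"].scale * rng.standard_normal()
        cur = np.sum(st.obs_loglik()) + priors.logpdf_exponential(np.exp(st.log_theta)) + st.log_theta
        new = np.sum(st.obs_loglik(log_theta=pz)) + priors.logpdf_exponential(np.exp(pz)) + pz
        acc = np.log(rng.random()) < new - cur
        if acc:
            st.log_theta = pz
        ad["theta"].record(acc)
    # distance coefficient
    pb = st.b + ad["b"].scale * rng.standard_normal()
    cur = np.sum(st.obs_loglik()) + priors.logpdf_normal(st.b)
    new = np.sum(st.obs_loglik(b=pb)) + priors.logpdf_normal(pb)
    acc = np.log(rng.random()) < new - cur
    if acc:
        st.b = pb
    ad["b"].record(acc)


def _level_p_move(st: _CountState, priors: PriorSet, ad: dict, rng) -> None:
    delta = ad["lvlp"].scale * rng.standard_normal()
    pa = st.alpha - st.beta * delta
    prop_p = st.logit_p - delta
    cur = (np.sum(st.obs_loglik()) + priors.logpdf_normal(st.alpha)
           + np.sum(np.log(_expit(st.logit_p)) + np.log(_expit(-st.logit_p))))
    new = (np.sum(st.obs_loglik(x=st.x + delta, logit_p=prop_p)) + priors.logpdf_normal(pa)
           + np.sum(np.log(_expit(prop_p)) + np.log(_expit(-prop_p))))
    acc = np.log(rng.random()) < new - cur
    if acc:
        st.x = st.x + delta
        st.alpha = pa
        st.logit_p = prop_p
    ad["lvlp"].record(acc)


# --------------------------------------------------------------------------
# public entry point
# --------------------------------------------------------------------------


def fit(spec: GaussianSSMSpec | CountSSMSpec, config: MCMCConfig,
        save_latents: bool = True) -> FitResult:
    """Sample the posterior of a state-space model specification.

    Returns a :class:`FitResult` with per-parameter chains, a
    :class:`PosteriorSummary` (mean, SD, equal-tailed 95% CI, R-hat) and,
    when ``save_latents``, joint draws of the latent state grid.
    """
    if isinstance(spec, GaussianSSMSpec):
        return _fit_gaussian(spec, config, save_latents)
    if isinstance(spec, CountSSMSpec):
        return _fit_count(spec, config, save_latents)
    raise TypeError(f"unknown model spec: {type(spec)!r}")
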