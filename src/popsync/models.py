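"""Declarative state-space model specifications and their likelihoods.

Two models are provided:

* Gaussian: log-abundance estimates with *assigned* per-record sampling
  variances and session random effects; Gompertz state process with
  ICC-structured process errors (shared variance sigma2_c, unshared
  sigma2_d; synchrony rho = sigma2_c / (sigma2_c + sigma2_d)).
* Count: replicated transect counts with imperfect detection; availability
  is negative-binomial (mean lambda, dispersion theta) with a log
  covered-distance covariate and session effects, thinned by binomial
  detection p_ij; Gompertz state process with GICC errors (per-site
  variances, shared fraction rho_prime).

The binomial thinning of an NB2 variable is again NB2 with the same
dispersion (thin a gamma-Poisson mixture and the gamma mixing is untouched),
so the availability N is marginalized analytically: the observation term is
a closed-form NB log-pmf with mean p*lambda and dispersion theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .panel import ObservationPanel, PanelValidationError

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class PriorSet:
    """The prior block shared by both models.

    Normal(0, V0) for alpha, beta and the distance coefficient b;
    InverseGamma(ig_shape, ig_rate) for all variance components;
    Uniform(0, 1) for rho_prime and each detection probability;
    Exponential(exp_rate) for the NB dispersion theta.
    """

    V0: float = 1000.0
    ig_shape: float = 0.001
    ig_rate: float = 0.001
    exp_rate: float = 1.0

    def logpdf_normal(self, value: float) -> float:
        return float(stats.norm.logpdf(value, 0.0, np.sqrt(self.V0)))

    def logpdf_invgamma(self, sigma2: float) -> float:
        if sigma2 <= 0:
            return -np.inf
        a, b = self.ig_shape, self.ig_rate
        return float(a * np.log(b) - special.gammaln(a)
                     - (a + 1.0) * np.log(sigma2) - b / sigma2)

    def logpdf_uniform01(self, value: float) -> float:
        return 0.0 if 0.0 <= value <= 1.0 else -np.inf

    def logpdf_exponential(self, theta: float) -> float:
        if theta <= 0:
            return -np.inf
        return float(np.log(self.exp_rate) - self.exp_rate * theta)


# --------------------------------------------------------------------------
# prepared panel indexes (shared with the MCMC engine)
# --------------------------------------------------------------------------


@dataclass
class PanelIndex:
    """Integer-coded view of a panel for fast likelihood evaluation."""

    rec_site: np.ndarray        # (n_rec,) site index
    rec_time: np.ndarray        # (n_rec,) time index (0-based)
    rec_session: np.ndarray     # (n_rec,) session index into the session table
    rec_value: np.ndarray       # (n_rec,) y or c
    rec_var: np.ndarray         # (n_rec,) assigned sampling variance (Gaussian)
    rec_logdist: np.ndarray     # (n_rec,) log covered distance (count)
    sess_site: np.ndarray       # (n_sess,) site of each session
    sess_time: np.ndarray       # (n_sess,) time of each session
    rec_sitetime: np.ndarray    # (n_rec,) index into the observed site-time table
    st_site: np.ndarray         # (n_st,) site of each observed site-time
    st_time: np.ndarray         # (n_st,) time of each observed site-time
    n_sites: int = 0
    n_times: int = 0


def build_panel_index(panel: ObservationPanel) -> PanelIndex:
    df = panel.data
    site_pos = {s: i for i, s in enumerate(panel.site_list)}
    time_pos = {t: j for j, t in enumerate(panel.time_grid)}
    rec_site = df["site"].map(site_pos).to_numpy(dtype=int)
    rec_time = df["time"].map(time_pos).to_numpy(dtype=int)
    sess_keys = list(zip(df["site"], df["time"], df["session"]))
    uniq = list(dict.fromkeys(sess_keys))
    sess_pos = {k: n for n, k in enumerate(uniq)}
    rec_session = np.array([sess_pos[k] for k in sess_keys], dtype=int)
    sess_site = np.array([site_pos[k[0]] for k in uniq], dtype=int)
    sess_time = np.array([time_pos[k[1]] for k in uniq], dtype=int)
    st_keys = list(zip(rec_site, rec_time))
    st_uniq = list(dict.fromkeys(st_keys))
    st_pos = {k: n for n, k in enumerate(st_uniq)}
    rec_sitetime = np.array([st_pos[k] for k in st_keys], dtype=int)
    st_site = np.array([k[0] for k in st_uniq], dtype=int)
    st_time = np.array([k[1] for k in st_uniq], dtype=int)
    return PanelIndex(
        rec_site=rec_site, rec_time=rec_time, rec_session=rec_session,
        rec_value=df["value"].to_numpy(dtype=float),
        rec_var=(df["sampling_sd"].to_numpy(dtype=float)) ** 2,
        rec_logdist=np.nan_to_num(df["log_distance"].to_numpy(dtype=float)),
        sess_site=sess_site, sess_time=sess_time,
        rec_sitetime=rec_sitetime, st_site=st_site, st_time=st_time,
        n_sites=panel.n_sites, n_times=panel.n_times,
    )


@dataclass
class GaussianSSMSpec:
    """Gaussian state-space model: assigned sampling variances, session
    effects, ICC process errors, shared Gompertz (alpha, beta)."""

    panel: ObservationPanel
    priors: PriorSet = field(default_factory=PriorSet)
    index: PanelIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.panel.data
        if (df["kind"] == "count").any():
            raise PanelValidationError("Gaussian model requires log_abundance records")
        if df["sampling_sd"].isna().any():
            raise PanelValidationError(
                "Gaussian model with assigned variances requires sampling_sd on every record")
        if self.panel.n_sites < 2:
            raise PanelValidationError("state-space synchrony model requires >= 2 sites")
        self.index = build_panel_index(self.panel)

    @property
    def parameter_names(self) -> list[str]:
        return ["alpha", "beta", "sigma2_c", "sigma2_d", "sigma2_gamma"]


@dataclass
class CountSSMSpec:
    """Count state-space model: thinned-NB observations with per-site-time
    detection, GICC process errors, shared Gompertz (alpha, beta)."""

    panel: ObservationPanel
    priors: PriorSet = field(default_factory=PriorSet)
    poisson_limit: bool = False
    fix_p: float | None = None      # freeze detection at a known value
    index: PanelIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.panel.data
        if (df["kind"] != "count").any():
            raise PanelValidationError("count model requires count records only")
        if df["log_distance"].isna().any():
            raise PanelValidationError("every count needs a log_distance covariate")
        if self.panel.n_sites < 2:
            raise PanelValidationError("state-space synchrony model requires >= 2 sites")
        self.index = build_panel_index(self.panel)
        counts_per_st = np.bincount(self.index.rec_sitetime)
        if (counts_per_st < 2).any():
            warnings.warn(
                "some site-times have < 2 counts: detection probability is weakly "
                "identified there (replicated counts drive the N-mixture logic)",
                stacklevel=2)

    @property
    def parameter_names(self) -> list[str]:
        names = ["alpha", "beta", "rho_prime", "sigma2_gamma", "theta", "b"]
        names += [f"sigma2_site[{s}]" for s in self.panel.site_list]
        return names


# --------------------------------------------------------------------------
# process-error (transition) log-density under compound-symmetric covariance
# --------------------------------------------------------------------------


def _compound_symmetry_logpdf(eps: np.ndarray, variances: np.ndarray,
                              shared_frac: float) -> float:
    """Sum of MVN log-densities of the columns of eps (n_sites, n_steps) under
    Sigma = D^1/2 [(1-rho)I + rho 11'] D^1/2, D = diag(variances)."""
    n = eps.shape[0]
    if np.any(variances <= 0) or not 0.0 <= shared_frac < 1.0:
        return -np.inf
    z = eps / np.sqrt(variances)[:, None]
    one_m = 1.0 - shared_frac
    denom = one_m + n * shared_frac
    # C^-1 = (I - rho/(denom) 11') / (1 - rho)
    colsum = z.sum(axis=0)
    quad = (np.sum(z * z) - shared_frac / denom * np.sum(colsum ** 2)) / one_m
    logdet = (np.sum(np.log(variances))
              + (n - 1) * np.log(one_m) + np.log(denom))
    n_steps = eps.shape[1]
    return float(-0.5 * (n_steps * (n * _LOG_2PI + logdet) + quad))


def transition_loglik(x: np.ndarray, alpha: float, beta: float,
                      variances: np.ndarray, shared_frac: float) -> float:
    """Gompertz transition log-density of a latent grid x (n_sites, n_times):
    eps_j = x_{j+1} - x_j - alpha - beta x_j, columns iid MVN with
    compound-symmetric covariance (ICC: equal variances and
    shared_frac = sigma2_c / total; GICC: per-site variances and rho_prime)."""
    eps = x[:, 1:] - x[:, :-1] - alpha - beta * x[:, :-1]
    return _compound_symmetry_logpdf(eps, np.asarray(variances, dtype=float),
                                     shared_frac)


# --------------------------------------------------------------------------
# Gaussian model log-likelihood
# --------------------------------------------------------------------------


def gaussian_loglik(params: dict, x: np.ndarray, spec: GaussianSSMSpec,
                    gammas: np.ndarray | None = None) -> float:
    """Conditional log-likelihood of the Gaussian model given latents.

    Sums Normal log-densities of each record y_ijf around x_ij + gamma_ijf
    with its assigned sampling variance, the N(0, sigma2_gamma) density of
    each session effect, and the ICC Gompertz transition densities.
    ``gammas=None`` omits session effects entirely (a no-gamma model).
    Site-times with no records contribute transition terms only.
    """
    idx = spec.index
    s2c, s2d = params["sigma2_c"], params["sigma2_d"]
    if s2d <= 0 or s2c < 0:
        raise ValueError("process variances must be positive (sigma2_d > 0, sigma2_c >= 0)")
    if np.any(idx.rec_var <= 0):
        raise ValueError("assigned sampling variances must be positive")
    mu = x[idx.rec_site, idx.rec_time]
    ll = 0.0
    if gammas is not None:
        s2g = params["sigma2_gamma"]
        if s2g <= 0:
            raise ValueError("sigma2_gamma must be positive when session effects are used")
        mu = mu + gammas[idx.rec_session]
        ll += float(np.sum(-0.5 * (_LOG_2PI + np.log(s2g) + gammas ** 2 / s2g)))
    resid = idx.rec_value - mu
    ll += float(np.sum(-0.5 * (_LOG_2PI + np.log(idx.rec_var)
                               + resid ** 2 / idx.rec_var)))
    total = s2c + s2d
    ll += transition_loglik(x, params["alpha"], params["beta"],
                            np.full(x.shape[0], total), s2c / total)
    return ll


# --------------------------------------------------------------------------
# count model log-likelihood
# --------------------------------------------------------------------------


def thinned_nb_logpmf(c, lam, theta, p, poisson_limit: bool = False):
    """Log-pmf of a binomially thinned NB2 count: availability
    N ~ NB(mean lam, dispersion theta) thinned by Binomial(N, p) gives
    c ~ NB(mean p*lam, dispersion theta) exactly (gamma-Poisson closure)."""
    c = np.asarray(c, dtype=float)
    mu = np.asarray(lam, dtype=float) * np.asarray(p, dtype=float)
    if poisson_limit:
        return c * np.log(mu) - mu - special.gammaln(c + 1.0)
    th = float(theta)
    return (special.gammaln(c + th) - special.gammaln(th) - special.gammaln(c + 1.0)
            + th * np.log(th / (th + mu)) + c * np.log(mu / (th + mu)))


def thinned_nb_logpmf_bruteforce(c: int, lam: float, theta: float, p: float,
                                 n_max: int | None = None) -> float:
    """Brute-force thinned-NB log-pmf by explicit summation over the latent
    availability N: sum_N NB(N; lam, theta) * Binomial(c; N, p).

    Independent of :func:`thinned_nb_logpmf`; used to cross-validate the
    closed-form marginalization on small cases.
    """
    if n_max is None:
        # the availability must reach ~c/p before the binomial term peaks,
        # so the truncation bound scales with 1/p as well as with lam
        n_max = int(c / max(p, 0.02) + 50 * max(lam, 1.0) + 100)
    ns = np.arange(c, n_max + 1)
    log_nb = stats.nbinom.logpmf(ns, theta, theta / (theta + lam))
    log_bin = stats.binom.logpmf(c, ns, p)
    return float(special.logsumexp(log_nb + log_bin))


def count_loglik(params: dict, x: np.ndarray, spec: CountSSMSpec,
                 gammas: np.ndarray | None = None,
                 p_sitetime: np.ndarray | None = None) -> float:
    """Conditional log-likelihood of the count model given latents.

    Observation terms are closed-form thinned-NB log-pmfs with mean
    p_ij * lambda, lambda = exp(x_ij + b * log_distance + gamma_ijf);
    plus session-effect and GICC transition densities.
    ``p_sitetime`` holds one detection probability per observed site-time
    (order of ``spec.index.st_site``); a scalar ``params["p"]`` may be used
    instead.
    """
    idx = spec.index
    theta = params.get("theta", np.inf)
    if not spec.poisson_limit and theta <= 0:
        raise ValueError("theta must be > 0")
    if p_sitetime is None:
        p_rec = np.full(idx.rec_value.size, float(params["p"]))
    else:
        p_rec = np.asarray(p_sitetime, dtype=float)[idx.rec_sitetime]
    if np.any(p_rec <= 0) or np.any(p_rec > 1):
        return -np.inf
    eta = x[idx.rec_site, idx.rec_time] + params.get("b", 0.0) * idx.rec_logdist
    ll = 0.0
    if gammas is not None:
        s2g = params["sigma2_gamma"]
        if s2g <= 0:
            raise ValueError("sigma2_gamma must be positive when session effects are used")
        eta = eta + gammas[idx.rec_session]
        ll += float(np.sum(-0.5 * (_LOG_2PI + np.log(s2g) + gammas ** 2 / s2g)))
    lam = np.exp(eta)
    ll += float(np.sum(thinned_nb_logpmf(idx.rec_value, lam, theta, p_rec,
                                         poisson_limit=spec.poisson_limit)))
    variances = np.asarray(params["sigma2_site"], dtype=float)
    ll += transition_loglik(x, params["alpha"], params["beta"],
                            variances, params["rho_prime"])
    return ll


# --------------------------------------------------------------------------
# derived synchrony
# --------------------------------------------------------------------------


def derive_synchrony(draws: dict[str, np.ndarray]) -> np.ndarray:
    """Per-draw synchrony: rho = sigma2_c / (sigma2_c + sigma2_d) for ICC
    draws, or the rho_prime draws themselves for GICC.

    Under identical linear density dependence and no dispersal this is also
    the average *population* synchrony (Moran identity); otherwise it is a
    lower bound on it.  Draws with sigma2_c + sigma2_d == 0 are excluded
    with a warning.
    """
    if "rho_prime" in draws:
        return np.asarray(draws["rho_prime"], dtype=float)
    s2c = np.asarray(draws["sigma2_c"], dtype=float)
    s2d = np.asarray(draws["sigma2_d"], dtype=float)
    total = s2c + s2d
    bad = total == 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} draws with zero total process variance",
                      stacklevel=2)
    return s2c[~bad] / total[~bad]
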