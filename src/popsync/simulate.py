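"""Superpopulation simulator: latent Gompertz dynamics and both sampling
processes.

The simulator realizes the stochastic process assumed to have generated the
observed series (the superpopulation model): log population sizes follow a
Gompertz (log-linear AR(1)) recursion with process errors partitioned into
shared and unshared components across sites — ICC when all sites share one
variance, GICC when variances differ — and observations arise from either a
Gaussian sampling process with session random effects or a binomially
thinned negative-binomial count process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (
    CountSampling,
    GaussianSampling,
    GICCError,
    ICCError,
    LatentStates,
    ObservationPanel,
    ProcessSpec,
)


@dataclass
class SimDesign:
    """Sampling design for a simulated panel.

    ``sessions_per_site_time`` and ``replicates_per_session`` may be scalars
    or (site x time) / per-session arrays; ``log_distances`` optionally
    supplies the covered-distance covariate for count sampling (scalar or
    per-count callable draw is handled by the count simulator).
    """

    n_sites: int
    n_times: int
    sessions_per_site_time: int | np.ndarray = 1
    replicates_per_session: int | np.ndarray = 1
    log_distances: float | None = None
    burn_in: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_times < 1:
            raise ValueError("n_sites and n_times must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    def sessions_at(self, i: int, j: int) -> int:
        s = np.asarray(self.sessions_per_site_time)
        return int(s) if s.ndim == 0 else int(s[i, j])

    def replicates_at(self, i: int, j: int, f: int) -> int:
        r = np.asarray(self.replicates_per_session)
        return int(r) if r.ndim == 0 else int(r[i, j])

    @property
    def site_list(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]

    @property
    def time_grid(self) -> list[int]:
        return list(range(1, self.n_times + 1))


def _rng(design: SimDesign, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    if design.seed is None:
        raise ValueError("a seed (or an explicit Generator) is required for simulation")
    return np.random.default_rng(design.seed)


def draw_process_errors(process: ProcessSpec, n_sites: int, n_steps: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw the (n_sites, n_steps) matrix of process errors eps_ij.

    ICC: eps_ij = c_j + d_ij with c_j ~ N(0, sigma2_c), d_ij ~ N(0, sigma2_d).
    GICC: eps_ij = sigma_i (sqrt(rho') u_j + sqrt(1-rho') v_ij) with u, v
    standard normal.
    """
    err = process.error
    if isinstance(err, ICCError):
        c = rng.normal(0.0, np.sqrt(err.sigma2_c), size=n_steps)
        d = rng.normal(0.0, np.sqrt(err.sigma2_d), size=(n_sites, n_steps))
        return c[None, :] + d
    if isinstance(err, GICCError):
        sigma = np.sqrt(err.total_variance(n_sites))
        u = rng.standard_normal(n_steps)
        v = rng.standard_normal((n_sites, n_steps))
        shared = np.sqrt(err.rho_prime) * u[None, :]
        unshared = np.sqrt(1.0 - err.rho_prime) * v
        return sigma[:, None] * (shared + unshared)
    raise TypeError(f"unknown process-error spec: {type(err)!r}")


def simulate_states(design: SimDesign, process: ProcessSpec,
                    rng: np.random.Generator | None = None) -> LatentStates:
    """Simulate latent log population sizes under the Gompertz recursion.

    States start at the stationary mean -alpha/beta (growth-rate form),
    run ``design.burn_in`` discarded steps, then record ``n_times`` values.
    |1 + beta| >= 1 is allowed but warns (nonstationary dynamics).
    """
    rng = _rng(design, rng)
    phi = process.ar_coefficient
    if abs(phi) >= 1.0:
        warnings.warn(f"|1 + beta| = {abs(phi):.3g} >= 1: nonstationary dynamics",
                      stacklevel=2)
        x0 = 0.0 if process.beta == 0 else process.stationary_mean
    else:
        x0 = process.stationary_mean
    n_steps = design.burn_in + design.n_times - 1
    eps = draw_process_errors(process, design.n_sites, max(n_steps, 0), rng)
    x = np.full(design.n_sites, x0, dtype=float)
    path = np.empty((design.n_sites, design.burn_in + design.n_times))
    path[:, 0] = x
    for t in range(n_steps):
        x = x + process.alpha + process.beta * x + eps[:, t]
        path[:, t + 1] = x
    recorded = path[:, design.burn_in:]
    return LatentStates(recorded, design.site_list, design.time_grid)


def simulate_gaussian_sampling(states: LatentStates, design: SimDesign,
                               sampling: GaussianSampling,
                               rng: np.random.Generator | None = None) -> ObservationPanel:
    """Observe latent states through the Gaussian sampling process:
    y_ijfk = x_ij + gamma_ijf + e_ijfk, with one session effect per
    (site, time, session) and sampling_sd = sqrt(sigma2_s) on every record."""
    rng = _rng(design, rng)
    sd_s = np.sqrt(sampling.sigma2_s)
    sd_g = np.sqrt(sampling.sigma2_gamma)
    rows = []
    for i in range(design.n_sites):
        for j in range(design.n_times):
            for f in range(design.sessions_at(i, j)):
                gamma = rng.normal(0.0, sd_g) if sd_g > 0 else 0.0
                for k in range(design.replicates_at(i, j, f)):
                    e = rng.normal(0.0, sd_s) if sd_s > 0 else 0.0
                    rows.append((states.site_list[i], states.time_grid[j],
                                 f + 1, k + 1, states.x[i, j] + gamma + e,
                                 "log_abundance", sd_s, np.nan))
    df = pd.DataFrame(rows, columns=["site", "time", "session", "replicate",
                                     "value", "kind", "sampling_sd", "log_distance"])
    return ObservationPanel(df, site_list=states.site_list, time_grid=states.time_grid)


def draw_negative_binomial(mean: float, theta: float, rng: np.random.Generator,
                           size=None, poisson_limit: bool = False) -> np.ndarray:
    """Draw NB2 counts (mean ``mean``, variance mean + mean^2/theta) via the
    gamma-Poisson mixture; exact Poisson draws in the Poisson limit."""
    if poisson_limit:
        return rng.poisson(mean, size=size)
    g = rng.gamma(shape=theta, scale=1.0 / theta, size=size)
    return rng.poisson(mean * g)


def simulate_count_sampling(states: LatentStates, design: SimDesign,
                            sampling: CountSampling,
                            rng: np.random.Generator | None = None) -> ObservationPanel:
    """Observe latent states through the count sampling process.

    Per count k in session f at (i, j):
    log lambda = x_ij + b * log_distance + gamma_ijf;
    availability N ~ NB(mean lambda, variance lambda + lambda^2/theta);
    observed count c ~ Binomial(N, p_ij).
    """
    rng = _rng(design, rng)
    sd_g = np.sqrt(sampling.sigma2_gamma)
    ld = 0.0 if design.log_distances is None else float(design.log_distances)
    rows = []
    for i in range(design.n_sites):
        for j in range(design.n_times):
            p_ij = sampling.p_at(i, j)
            for f in range(design.sessions_at(i, j)):
                gamma = rng.normal(0.0, sd_g) if sd_g > 0 else 0.0
                for k in range(design.replicates_at(i, j, f)):
                    lam = np.exp(states.x[i, j] + sampling.b * ld + gamma)
                    n_avail = draw_negative_binomial(
                        lam, sampling.theta, rng,
                        poisson_limit=sampling.poisson_limit)
                    c = rng.binomial(int(n_avail), p_ij)
                    rows.append((states.site_list[i], states.time_grid[j],
                                 f + 1, k + 1, float(c), "count", np.nan, ld))
    df = pd.DataFrame(rows, columns=["site", "time", "session", "replicate",
                                     "value", "kind", "sampling_sd", "log_distance"])
    return ObservationPanel(df, site_list=states.site_list, time_grid=states.time_grid)
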