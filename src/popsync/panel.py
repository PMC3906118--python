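"""Data model, validation and I/O for replicated abundance panels.

A *panel* holds long-format observations of population abundance indexed by
(site, time, session, replicate).  Two observation kinds are supported:

``log_abundance``
    Gaussian population-size estimates on the log scale (e.g. log CPUE),
    optionally carrying an assigned per-record sampling standard deviation.
``count``
    Non-negative integer counts (e.g. transect counts of animals),
    optionally carrying a log covered-distance covariate.

Sites are strings; time, session and replicate are 1-based integers.  The
time grid is regular and shared across sites; site-times with no sessions
are treated as latent-only (the state is still simulated or estimated, but
contributes no likelihood term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

PANEL_COLUMNS = [
    "site", "time", "session", "replicate",
    "value", "kind", "sampling_sd", "log_distance",
]

SUMMARY_COLUMNS = ["name", "mean", "sd", "ci2.5", "ci97.5", "rhat"]


class PanelValidationError(ValueError):
    """Raised when a panel violates a structural invariant."""


@dataclass
class ObservationPanel:
    """Long-format replicated abundance observations.

    Parameters
    ----------
    data
        DataFrame with columns ``site, time, session, replicate, value,
        kind, sampling_sd, log_distance``; ``sampling_sd`` and
        ``log_distance`` may be NaN where absent.
    site_list, time_grid
        Optional explicit site and time universes.  When omitted they are
        inferred from the records.  Supplying a larger grid than the data
        declares latent-only site-times.
    """

    data: pd.DataFrame
    site_list: list[str] | None = None
    time_grid: list[int] | None = None

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in ("site", "time", "session", "replicate", "value", "kind")
                   if c not in df.columns]
        if missing:
            raise PanelValidationError(f"missing required columns: {missing}")
        for col in ("sampling_sd", "log_distance"):
            if col not in df.columns:
                df[col] = np.nan
        df = df[PANEL_COLUMNS].reset_index(drop=True)
        df["site"] = df["site"].astype(str)
        for col in ("value", "sampling_sd", "log_distance"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        for col in ("time", "session", "replicate"):
            df[col] = df[col].astype(int)
            bad = df.index[df[col] < 1]
            if len(bad):
                raise PanelValidationError(
                    f"column {col!r} must be >= 1; offending rows: {list(bad[:10])}")
        bad_kind = df.index[~df["kind"].isin(["log_abundance", "count"])]
        if len(bad_kind):
            raise PanelValidationError(
                f"unknown kind; offending rows: {list(bad_kind[:10])}")

        counts = df["kind"] == "count"
        vals = df.loc[counts, "value"]
        noninteger = vals.index[(vals < 0) | (vals != np.floor(vals))]
        if len(noninteger):
            raise PanelValidationError(
                "count records must be non-negative integers; offending rows: "
                f"{list(noninteger[:10])}")
        gauss = df.loc[~counts, "value"]
        nonfinite = gauss.index[~np.isfinite(gauss)]
        if len(nonfinite):
            raise PanelValidationError(
                f"log_abundance values must be finite; offending rows: {list(nonfinite[:10])}")
        sd = df["sampling_sd"]
        bad_sd = sd.index[sd.notna() & (sd < 0)]
        if len(bad_sd):
            raise PanelValidationError(
                f"sampling_sd must be non-negative; offending rows: {list(bad_sd[:10])}")

        dup = df.duplicated(subset=["site", "time", "session", "replicate"])
        if dup.any():
            raise PanelValidationError(
                "duplicate (site, time, session, replicate) keys; offending rows: "
                f"{list(df.index[dup][:10])}")

        self.data = df
        if self.site_list is None:
            self.site_list = sorted(df["site"].unique())
        else:
            self.site_list = [str(s) for s in self.site_list]
            extra = set(df["site"]) - set(self.site_list)
            if extra:
                raise PanelValidationError(f"records reference sites outside site_list: {extra}")
        if self.time_grid is None:
            tmax = int(df["time"].max()) if len(df) else 1
            self.time_grid = list(range(1, tmax + 1))
        else:
            self.time_grid = [int(t) for t in self.time_grid]
            extra_t = set(df["time"]) - set(self.time_grid)
            if extra_t:
                raise PanelValidationError(f"records reference times outside time_grid: {extra_t}")

    # -- properties ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.site_list)

    @property
    def n_times(self) -> int:
        return len(self.time_grid)

    @property
    def gaussian_ready(self) -> bool:
        """True when every log_abundance record carries an assigned sampling SD."""
        g = self.data[self.data["kind"] == "log_abundance"]
        return len(g) > 0 and g["sampling_sd"].notna().all()

    def require_synchrony_shape(self) -> None:
        """Synchrony estimation needs >= 2 sites and >= 3 time points."""
        if self.n_sites < 2 or self.n_times < 3:
            raise PanelValidationError(
                f"synchrony estimation requires >= 2 sites and >= 3 times; "
                f"got {self.n_sites} sites, {self.n_times} times")

    def site_time_means(self) -> pd.DataFrame:
        """Per-(site, time) mean of values — a quick summary grid."""
        return (self.data.groupby(["site", "time"], as_index=False)["value"].mean())

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationPanel):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.data, other.data, check_exact=False)
        except AssertionError:
            return False
        return self.site_list == other.site_list and self.time_grid == other.time_grid


def read_panel(path, site_list: Sequence[str] | None = None,
               time_grid: Sequence[int] | None = None) -> ObservationPanel:
    """Read a panel CSV (columns site,time,session,replicate,value,kind,
    sampling_sd,log_distance) into a validated :class:`ObservationPanel`."""
    df = pd.read_csv(path)
    return ObservationPanel(df,
                            site_list=list(site_list) if site_list is not None else None,
                            time_grid=list(time_grid) if time_grid is not None else None)


def write_panel(panel: ObservationPanel, path) -> None:
    panel.to_csv(path)


@dataclass
class LatentStates:
    """True log population sizes on a site x time grid.

    ``x[i, j]`` is the log population size of ``site_list[i]`` at
    ``time_grid[j]``; ``mask[i, j]`` is True where the state is regarded as
    unobserved (latent-only).
    """

    x: np.ndarray
    site_list: list[str]
    time_grid: list[int]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (len(self.site_list), len(self.time_grid)):
            raise PanelValidationError(
                f"state matrix shape {self.x.shape} does not match "
                f"{len(self.site_list)} sites x {len(self.time_grid)} times")
        if self.mask is None:
            self.mask = np.zeros_like(self.x, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.x.shape:
                raise PanelValidationError("mask shape does not match state matrix")

    def increments(self) -> np.ndarray:
        """First differences x[:, 1:] - x[:, :-1] (log growth rates)."""
        return np.diff(self.x, axis=1)


def write_states(states: LatentStates, path) -> None:
    """Write latent states as long-format CSV (site,time,x,masked)."""
    ns, nt = states.x.shape
    df = pd.DataFrame({
        "site": np.repeat(states.site_list, nt),
        "time": np.tile(states.time_grid, ns),
        "x": states.x.ravel(),
        "masked": states.mask.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def read_states(path) -> LatentStates:
    df = pd.read_csv(path)
    sites = list(dict.fromkeys(df["site"].astype(str)))
    times = sorted(df["time"].unique())
    piv = df.pivot(index="site", columns="time", values="x").loc[sites, times]
    msk = df.pivot(index="site", columns="time", values="masked").loc[sites, times]
    return LatentStates(piv.to_numpy(), sites, [int(t) for t in times],
                        mask=msk.to_numpy().astype(bool))


# -- process / sampling specifications ----------------------------------


@dataclass
class ICCError:
    """Process error split into shared + unshared components with a common
    site variance: eps_ij = c_j + d_ij, c_j ~ N(0, sigma2_c),
    d_ij ~ N(0, sigma2_d).  The intra-class correlation
    rho = sigma2_c / (sigma2_c + sigma2_d) is the average process synchrony."""

    sigma2_c: float
    sigma2_d: float

    def __post_init__(self) -> None:
        if self.sigma2_c < 0 or self.sigma2_d < 0:
            raise ValueError("ICC variance components must be >= 0")

    @property
    def rho(self) -> float:
        tot = self.sigma2_c + self.sigma2_d
        if tot == 0:
            raise ValueError("ICC undefined when sigma2_c + sigma2_d == 0")
        return self.sigma2_c / tot

    def total_variance(self, n_sites: int) -> np.ndarray:
        return np.full(n_sites, self.sigma2_c + self.sigma2_d)


@dataclass
class GICCError:
    """Generalised ICC process error: each site has its own residual process
    variance sigma2_site[i], a fraction rho_prime of which is shared:
    eps_ij = sigma_i * (sqrt(rho') u_j + sqrt(1 - rho') v_ij)."""

    sigma2_site: np.ndarray
    rho_prime: float

    def __post_init__(self) -> None:
        self.sigma2_site = np.asarray(self.sigma2_site, dtype=float)
        if np.any(self.sigma2_site < 0):
            raise ValueError("per-site variances must be >= 0")
        if not 0.0 <= self.rho_prime <= 1.0:
            raise ValueError("rho_prime must lie in [0, 1]")

    def total_variance(self, n_sites: int) -> np.ndarray:
        if self.sigma2_site.size == 1:
            return np.full(n_sites, float(self.sigma2_site))
        if self.sigma2_site.size != n_sites:
            raise ValueError("sigma2_site length does not match number of sites")
        return self.sigma2_site


@dataclass
class ProcessSpec:
    """Gompertz density dependence plus a process-error decomposition.

    The state recursion (growth-rate form) is
    ``x_{t} = x_{t-1} + alpha + beta * x_{t-1} + eps_t``,
    i.e. an AR(1) on the log scale with slope ``1 + beta``.
    """

    alpha: float
    beta: float
    error: ICCError | GICCError

    @property
    def ar_coefficient(self) -> float:
        return 1.0 + self.beta

    @property
    def stationary_mean(self) -> float:
        if self.beta == 0:
            raise ValueError("stationary mean undefined for beta == 0 (random walk)")
        return -self.alpha / self.beta


@dataclass
class GaussianSampling:
    """Gaussian sampling process: y_ijf = x_ij + gamma_ijf + e_ijf with
    session effects gamma ~ N(0, sigma2_gamma) and within-session error
    e ~ N(0, sigma2_s)."""

    sigma2_s: float
    sigma2_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_s < 0 or self.sigma2_gamma < 0:
            raise ValueError("sampling variances must be >= 0")


@dataclass
class CountSampling:
    """Overdispersed count sampling: availability N ~ NB(mean lambda,
    variance lambda + lambda^2/theta) with log lambda = x + b*log_distance
    + gamma, thinned by binomial detection with probability p.

    ``p`` is either a scalar or a (site x time) array of detection
    probabilities; ``poisson_limit`` replaces the NB by a Poisson
    (theta -> infinity)."""

    theta: float
    p: float | np.ndarray
    b: float = 0.0
    sigma2_gamma: float = 0.0
    poisson_limit: bool = False

    def __post_init__(self) -> None:
        if not self.poisson_limit and self.theta <= 0:
            raise ValueError("theta must be > 0 (or set poisson_limit=True)")
        p = np.asarray(self.p, dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("detection probabilities must lie in (0, 1]")
        if self.sigma2_gamma < 0:
            raise ValueError("sigma2_gamma must be >= 0")

    def p_at(self, i: int, j: int) -> float:
        p = np.asarray(self.p, dtype=float)
        if p.ndim == 0:
            return float(p)
        return float(p[i, j])


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, SD, equal-tailed 95% CI and R-hat."""

    table: pd.DataFrame
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        need = {"name", "mean", "sd", "ci2.5", "ci97.5"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")
        if "rhat" not in self.table.columns:
            self.table["rhat"] = np.nan
        bad = self.table["ci2.5"] > self.table["ci97.5"]
        if bad.any():
            raise ValueError("ci2.5 must not exceed ci97.5")

    def __getitem__(self, name: str) -> pd.Series:
        row = self.table[self.table["name"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])


def write_summary(summary: PosteriorSummary, path) -> None:
    summary.table[SUMMARY_COLUMNS].to_csv(path, index=False)


def read_summary(path) -> PosteriorSummary:
    df = pd.read_csv(path)
    return PosteriorSummary(df)


def log_transform_cpue(values, offset="auto"):
    """Log-transform non-negative abundance indices as log(value + offset).

    ``offset="auto"`` uses the smallest positive value in the series —
    the convention used for catch-per-unit-effort series where 0.2 was the
    minimal non-zero catch.  All-zero series have no defined auto offset.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("abundance indices must be >= 0")
    if offset == "auto":
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("auto offset undefined for an all-zero series")
        offset = float(positive.min())
    offset = float(offset)
    if offset <= 0 or not math.isfinite(offset):
        raise ValueError("offset must be a positive finite number")
    return np.log(values + offset)
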