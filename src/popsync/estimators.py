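"""Naive and attenuation-corrected synchrony estimators.

Two populations observed with independent additive sampling error of
variance v_s appear less synchronous than they are: the zero-lag Pearson
correlation of the observed series has expectation roughly
rho * (1 - v_s / V_total), where V_total is the total temporal variance
(process + sampling).  When an external estimate of v_s is available the
attenuation can be undone by rescaling the covariance with the de-noised
variances, cov / sqrt((V_i - v_s)(V_i' - v_s)).

This module also provides the conditional-least-squares Gompertz fit and
the average residual correlation used by the naive (process-error-only)
synchrony workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np


class DegenerateSeriesError(ValueError):
    """A series is constant / too short for a correlation or fit."""


@dataclass
class CorrectedCorrelation:
    """Attenuation-corrected correlation; may exceed |1| in noisy samples."""

    value: float
    out_of_range: bool

    def __float__(self) -> float:
        return self.value


@dataclass
class CorrelationReport:
    """Pairwise correlations between sites and their arithmetic mean."""

    pairwise: dict[tuple[str, str], float]
    average: float
    n_times: int


@dataclass
class GompertzFit:
    """Conditional least-squares Gompertz fit of a log-abundance series."""

    alpha: float
    beta: float
    residuals: np.ndarray  # aligned with times 2..T; NaN where a lag pair is missing
    form: str = "growth_rate"


def _complete_pairs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def zero_lag_corr(y_i, y_iprime) -> float:
    """Pearson correlation at lag zero, pairwise-complete over gaps (NaN)."""
    a = np.asarray(y_i, dtype=float)
    b = np.asarray(y_iprime, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    a, b = _complete_pairs(a, b)
    if a.size < 3:
        raise DegenerateSeriesError("need >= 3 complete time points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateSeriesError("correlation undefined for a constant series")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def attenuation_corrected_corr(y_i, y_iprime, v_s: float) -> CorrectedCorrelation:
    """Correct the zero-lag correlation for additive sampling error.

    Assumes sampling errors are additive, independent between populations
    and of constant variance ``v_s``.  Returns
    cov(y, y') / sqrt((V - v_s)(V' - v_s)) untruncated; ``out_of_range``
    flags estimates outside [-1, 1].
    """
    if v_s < 0:
        raise ValueError("sampling variance must be >= 0")
    a = np.asarray(y_i, dtype=float)
    b = np.asarray(y_iprime, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    a, b = _complete_pairs(a, b)
    if a.size < 3:
        raise DegenerateSeriesError("need >= 3 complete time points")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if v_s >= min(va, vb):
        raise DegenerateSeriesError(
            f"correction undefined: v_s={v_s:.4g} >= min sample variance "
            f"{min(va, vb):.4g}")
    cov = np.cov(a, b, ddof=1)[0, 1]
    r = float(cov / np.sqrt((va - v_s) * (vb - v_s)))
    return CorrectedCorrelation(value=r, out_of_range=abs(r) > 1.0)


def expected_attenuation(ratio: float) -> float:
    """Multiplicative bias factor 1 - ratio of the naive correlation.

    ``ratio`` is the contribution of sampling variance to the total temporal
    variance, v_s / V_total; the naive estimator has expectation
    rho * (1 - ratio) when both sites share the same constant ratio.
    """
    if not 0.0 <= ratio < 1.0:
        raise ValueError("ratio must lie in [0, 1)")
    return 1.0 - ratio


def gompertz_cls_fit(series, form: str = "growth_rate") -> GompertzFit:
    """Fit a Gompertz (log-linear AR(1)) model by conditional least squares.

    In the default growth-rate form the regression is
    ``x_t - x_{t-1} = alpha + beta * x_{t-1} + eps_t`` so the AR(1) slope is
    ``1 + beta`` and ``beta`` is the density-dependence coefficient.  With
    ``form="raw"`` the regression is ``x_t = alpha + beta * x_{t-1}``.
    Gaps (NaN) drop the lag pairs they break; no imputation.
    """
    if form not in ("growth_rate", "raw"):
        raise ValueError("form must be 'growth_rate' or 'raw'")
    x = np.asarray(series, dtype=float)
    lag, lead = x[:-1], x[1:]
    ok = np.isfinite(lag) & np.isfinite(lead)
    if ok.sum() < 3:
        raise DegenerateSeriesError("need >= 3 complete lag pairs (length >= 4)")
    xl = lag[ok]
    if np.ptp(xl) == 0:
        raise DegenerateSeriesError("zero-variance predictor")
    resp = (lead - lag)[ok] if form == "growth_rate" else lead[ok]
    X = np.column_stack([np.ones(xl.size), xl])
    coef, *_ = np.linalg.lstsq(X, resp, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    residuals = np.full(x.size - 1, np.nan)
    residuals[ok] = resp - X @ coef
    return GompertzFit(alpha=alpha, beta=beta, residuals=residuals, form=form)


def avg_residual_corr(series_by_site: dict[str, np.ndarray] | np.ndarray,
                      form: str = "growth_rate") -> CorrelationReport:
    """Gompertz-fit each site's series and average the pairwise residual
    correlations over the n(n-1)/2 site pairs."""
    if isinstance(series_by_site, dict):
        items = list(series_by_site.items())
    else:
        arr = np.asarray(series_by_site, dtype=float)
        items = [(str(i), arr[i]) for i in range(arr.shape[0])]
    if len(items) < 2:
        raise ValueError("need >= 2 sites")
    residuals = {name: gompertz_cls_fit(s, form=form).residuals for name, s in items}
    pairwise: dict[tuple[str, str], float] = {}
    for (na, ra), (nb, rb) in combinations(residuals.items(), 2):
        pairwise[(na, nb)] = zero_lag_corr(ra, rb)
    n_times = max(len(s) for _, s in items)
    return CorrelationReport(pairwise=pairwise,
                             average=float(np.mean(list(pairwise.values()))),
                             n_times=n_times)


def residual_corr_matrix(residuals: np.ndarray) -> np.ndarray:
    """Site x site correlation matrix of residual process-variation series.

    ``residuals`` is (n_sites, n_times), e.g. posterior means of the state
    residuals from a fitted state-space model; supports detection of
    negative synchrony that the ICC/GICC parametrizations cannot express.
    Pairwise-complete over NaN gaps; unit diagonal; symmetric.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.shape[0]
    out = np.eye(n)
    for i, j in combinations(range(n), 2):
        out[i, j] = out[j, i] = zero_lag_corr(r[i], r[j])
    return out
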