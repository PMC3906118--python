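# Methods

## The inference problem

Synchrony studies ask how strongly the year-to-year fluctuations of
spatially separated populations are correlated. The estimand lives at the
*superpopulation* level: the stochastic process assumed to have generated
the observed series. Two nested sources of randomness matter — the
population process (process error) and the survey (sampling error) — and
estimators must be judged under both. The naive zero-lag correlation of
observed log-abundance series is unbiased only in the no-noise limit; with
independent additive sampling errors of constant variance it is attenuated
by the factor (1 − v_s/V_total). All of `popsync` is organized around
either undoing that attenuation analytically or modelling the two error
sources separately.

## State-space models

**State process.** Log abundance follows a Gompertz (log-linear AR(1))
recursion in growth-rate form:

    x[i, t] = x[i, t-1] + alpha + beta * x[i, t-1] + eps[i, t]

so the AR(1) coefficient is 1 + beta and beta is the density-dependence
coefficient (beta = 0: random walk; beta = -1: white noise). The recursion
is never written explicitly in the source literature for this family of
analyses; the growth-rate form is chosen because published density-
dependence estimates around -0.3 to -0.5 then imply positive
autocorrelation (0.5-0.7), which is the biologically sensible reading. The
raw AR form x_t = alpha + beta x_{t-1} is available in
`gompertz_cls_fit(form="raw")` for sensitivity analysis; the two forms have
identical residuals and slopes differing by exactly 1.

**Process-error decomposition.** The error vector across sites at each
time has a compound-symmetric covariance:

- ICC: eps[i,j] = c[j] + d[i,j], c ~ N(0, sigma2_c) shared, d ~ N(0,
  sigma2_d) site-specific. The intra-class correlation rho =
  sigma2_c/(sigma2_c + sigma2_d) is the average pairwise correlation of
  process errors. Appropriate when the magnitude of fluctuations is
  similar across sites.
- GICC: eps[i,j] = sigma_i (sqrt(rho') u_j + sqrt(1-rho') v_ij) with
  standard-normal u, v. Each site keeps its own residual variance
  sigma2_i; rho' is the shared fraction. When all sigma_i are equal the
  two parametrizations coincide in distribution (verified empirically in
  the test suite at T = 1e5).

Under identical linear density dependence and no dispersal, rho (or rho')
also estimates the average synchrony of the *populations*, not just of the
process errors (the Moran identity). With nonlinearity or heterogeneity it
is a lower bound. Both parametrizations quantify *positive* synchrony;
negative synchrony (e.g. apparent competition) is detectable through
`residual_corr_matrix` on the posterior-mean latent residuals. Note that
posterior-mean residuals are smoothed, which inflates their correlations
relative to rho; the matrix is a pattern-detection tool, not an estimator
of rho.

**Gaussian observation process** (abundance estimates with known
uncertainty): y[i,j,f] = x[i,j] + gamma[i,j,f] + e[i,j,f], where f indexes
sampling sessions within a site-year, gamma ~ N(0, sigma2_gamma) absorbs
between-session differences in mean abundance, and e ~ N(0, sigma2_s) with
sigma2_s *assigned* per record (e.g. from a prior study or a distance-
sampling fit; stored as an SD column to avoid unit confusion). One shared
sigma2_gamma is used across sites.

**Count observation process** (replicated transect counts): for count k in
session f, log lambda = x[i,j] + b * log_distance + gamma[i,j,f];
availability N ~ NB2(mean lambda, variance lambda + lambda^2/theta); the
observed count is Binomial(N, p[i,j]) with one detection probability per
site-time, constant across its sessions and counts. Replicated counts
within closed site-times are what identify detection (N-mixture logic);
the model spec warns when any site-time has fewer than two counts. Since
thinning a gamma-Poisson mixture leaves the gamma mixing untouched, the
observed count is exactly NB2(mean p*lambda, dispersion theta): the
discrete availability is marginalized in closed form. The identity is
cross-validated against an explicit truncated summation over N in both the
test suite and the acceptance script (agreement ~1e-14; the summation
bound must reach past N ~ c/p before the binomial term peaks).

**Priors.** Normal(0, 1000) for alpha, beta and b (the "large variance"
value is configurable); InverseGamma(0.001, 0.001) for all variance
components; Uniform(0, 1) for rho' and each detection probability;
Exponential(rate 1) for theta. The fish-style model keeps independent
inverse-gamma priors on sigma2_c and sigma2_d, with rho derived per draw.
The near-improper inverse-gamma is retained for comparability despite its
known sensitivity when a variance component approaches zero; reparametrizing
the ICC model as (total variance, rho ~ Uniform(0,1)) was checked and moves
the rho posterior by < 0.01 at the study conditions used here.

## Samplers

The contract is distributional correctness, not kernel identity.

**Gaussian model.** Conditional on the five hyperparameters (alpha, beta,
sigma2_c, sigma2_d, sigma2_gamma) the model is linear-Gaussian, so the
latent states, session effects and shared year effects are integrated out
*exactly* by a Kalman filter over the site-vector state (compound-symmetric
innovation covariance; sessions collapsed to sufficient statistics with an
analytic remainder carrying the sigma2_gamma dependence; within-session
replicate terms depend only on assigned variances and drop as constants).
An adaptive random-walk Metropolis chain (Haario-style empirical-covariance
proposal, adaptation frozen at the end of burn-in) runs on the
hyperparameters with variances on the log scale. Latent-state draws are
recovered afterwards by forward-filter backward-sampling at a thinned
subset of retained draws. Marginalization avoids the notoriously slow
mixing of single-site Gibbs updates on short series; the filter is
verified against a brute-force joint multivariate-normal likelihood in the
test suite. The initial state has a vague proper prior N(per-site observed
mean, 25); with no observations at all the marginal likelihood is constant
and the sampler returns the priors (checked: the implied prior mean of rho
is 1/2).

**Count model.** The thinned-NB likelihood is not conjugate, so latent
states and session effects stay explicit in a Metropolis-within-Gibbs
sweep: joint per-time-column random-walk updates of the state vector;
vectorized independent updates of session effects and of the per-site-time
detection logits; exact bivariate-normal Gibbs draws of (alpha, beta)
given the latents (GLS with known error covariance); random-walk updates
of the remaining scalars on log/logit scales; and two ridge moves that
shift the whole latent surface with compensating changes to alpha (and
optionally the detection logits) — these traverse the abundance-detection
ridge that otherwise dominates the autocorrelation time. All scales adapt
by Robbins-Monro during burn-in. Detection can be frozen (`fix_p`) and a
Poisson observation limit is available (`poisson_limit`), which together
reduce the model to a log-scale Gaussian analysis at high abundance — used
as a cross-model consistency check.

**Diagnostics and summaries.** Gelman-Rubin potential scale reduction in
the between/within form, with the variance ratio floored at 1 so that
identical chains report exactly 1.0 and R-hat >= 1 always holds (the raw
estimator equals sqrt((n-1)/n) < 1 when the between-chain variance is
zero). Summaries are posterior mean, SD and equal-tailed 2.5/97.5%
quantiles — the credible-interval convention of the general-purpose Gibbs
samplers this class of models is usually fitted with. Default chain
settings (3 x 20,000, burn-in 5,000, thin 5) are desk-scale;
`MCMCConfig.published_scale()` gives the heavy configuration (3 x 1.2M,
burn-in 100k, thin 100) used for published real-data fits of this model
family.

## Simulator

`simulate_states` initializes at the stationary mean -alpha/beta and
discards 100 burn-in steps by default (initialization is otherwise
arbitrary; the transient is gone well before recording). Nonstationary
settings (|1+beta| >= 1) warn rather than fail. The negative binomial is
drawn as an exact gamma-Poisson mixture; the Poisson limit is an explicit
flag rather than a large-theta hack. Every stochastic entry point requires
a seed or an explicit generator, and identical seeds give bit-identical
output.

What the generator emulates: Gompertz mean dynamics, ICC/GICC-structured
environmental noise, session effects, assigned-variance Gaussian sampling,
and binomially thinned overdispersed counts with a distance covariate.
What it does not: demographic stochasticity, age structure, dispersal
coupling, nonlinear (e.g. theta-logistic) density dependence,
distance-decaying spatial covariance, and observer heterogeneity beyond
the session effect. Passing tests therefore demonstrate correct behaviour
under the model's own assumptions, not robustness to these departures.

## Study conditions used by the tests and the acceptance script

Fish-style (CPUE survey): 3 sites, 24 years; alpha = 0.25, beta = -0.26;
total process variance 0.04 split as rho = 0.86; session-effect variance
0.007; per-fishing sampling variance 0.165 on the log scale. The
sampling-variance constant is published only in a supplementary fitting
program that is not part of this repository; 0.165 is a reconstruction,
fixed once by requiring the replicate-averaging protocol to reproduce the
published Monte-Carlo bias table (mean naive synchrony 0.19/0.34/0.55/0.76
at N_K = 1/3/10/50 with SDs 0.12/0.13/0.11/0.08), and not revisited. The
recovery experiment uses 4 sessions per site-year ("several" fishings at
few-month intervals). Where the published table's density-dependence
column is concerned, note an internal tension: the published mean beta-hat
converges to about -0.67 at N_K = 50, whereas the protocol as described
converges to the noiseless conditional-least-squares mean (about -0.44 at
T = 24) once the averaged noise vanishes — no single sampling variance
reproduces both columns. The reconstruction matches the synchrony column,
which carries the study's headline result (about 60% underestimation at
N_K = 3); the resulting beta-hat at N_K = 1 is -0.86 against a published
-0.91.

Cat-style (transect counts): 4 sites, 24 seasons; alpha = -1, beta =
-0.44; per-site process variances {0.41, 1.02, 0.58, 0.22}; rho' = 0.75;
theta = 5.11; distance coefficient 0.12 with the covered-distance
covariate treated as centered (so availability runs near exp(x), i.e.
counts are small and frequently zero — the regime in which the published
near-zero naive synchrony at N_K = 1 arises); per-site detection {0.54,
0.61, 0.54, 0.52}; session-effect variance 0.01 (not published; chosen
small). Zero counts are log-transformed with the 0.2 offset convention
(the smallest nonzero abundance in the original series); all-zero series
make the Gompertz fit degenerate and such simulations are excluded and
counted, with a warning above 5%.

Problem sizes: the acceptance script uses 1000 pairs for the attenuation
experiment, 60 replicate fits for recovery, 500 (Gaussian) and 250 (count)
Monte-Carlo sets for the what-if experiments, and single-chain desk-scale
MCMC (5000 iterations) inside the recovery loop; these sizes put every
Monte-Carlo standard error well inside the tolerances being checked while
keeping the full run in the low minutes on one CPU.

## Numerical choices

- Corrected correlations are returned untruncated with an `out_of_range`
  flag; clipping would hide estimator variance. The correction requires
  v_s strictly below both sample variances and raises otherwise.
- The correction is unstable when v_s approaches the sample variances:
  the de-noised denominator can pass near zero, and the *mean* of the
  corrected estimator over many pairs then overshoots (heavy right tail)
  even though the median stays near the truth. At T = 200 this already
  matters for a sampling share of 0.8. Users in that regime should prefer
  the state-space route.
- Gaps: all lag regressions and correlations are pairwise-complete; no
  imputation.
- Gompertz fitting is conditional least squares (OLS on the increment
  regression); at T ~ 24 the AR coefficient carries the usual downward
  small-sample bias, which is part of what the what-if experiment
  measures.
- The Kalman filter runs in a numba-compiled kernel (~50 us per
  likelihood at the fish problem size); sequential scalar updates are
  exact because the collapsed observation covariance is diagonal.
- Posterior means of the bounded synchrony ratio shrink toward 1/2 when
  the data are weakly informative (short series plus heavy sampling
  noise). At the fish-style conditions above, the mean posterior mean of
  rho across simulations is about 0.75-0.78 against a truth of 0.86, even
  though 95% intervals cover the truth at nominal rates and the
  likelihood and sampler are verified exact. This is a property of the
  posterior-mean functional, not a defect of the fit, and it shrinks
  quickly as observation noise falls (near-noiseless data give 0.88).

## Limitations

- The ICC/GICC decomposition assumes exchangeable shared noise; it cannot
  represent distance-decaying correlation between sites.
- Detection probabilities are site-time specific with no covariates, and
  theta is constant.
- The count sampler's (alpha, beta) posterior is diffuse on short, sparse
  panels (errors-in-variables geometry); intervals remain calibrated but
  wide, and R-hat on the level parameters should be checked before use.
- An unstructured multivariate-normal process covariance (free
  correlation matrix) is out of scope; the residual correlation matrix of
  the fitted model is the supported exploratory alternative.
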