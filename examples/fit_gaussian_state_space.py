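"""Fitting the Gaussian state-space model to a replicated abundance panel.

Simulates a fish-style survey — 3 sites, 24 years, 4 sampling sessions per
site-year, each log-abundance estimate carrying an assigned sampling SD —
then fits the Gompertz state-space model with ICC process errors and prints
the posterior summary.  The synchrony parameter rho is the shared fraction
of the process variance; the naive residual-correlation estimate of the
same quantity is shown for contrast.
"""

import numpy as np

import popsync as ps

process = ps.ProcessSpec(alpha=0.25, beta=-0.26,
                         error=ps.ICCError(sigma2_c=0.0344, sigma2_d=0.0056))
design = ps.SimDesign(n_sites=3, n_times=24, sessions_per_site_time=4, seed=11)
states = ps.simulate_states(design, process)
panel = ps.simulate_gaussian_sampling(
    states, design, ps.GaussianSampling(sigma2_s=0.165, sigma2_gamma=0.007),
    rng=np.random.default_rng(12))

spec = ps.GaussianSSMSpec(panel)
result = ps.fit(spec, ps.MCMCConfig(n_chains=3, n_iter=6000, n_burnin=2500,
                                    thin=3, seed=13))

print(result.summary.table.round(3).to_string(index=False))
print()
grid = panel.site_time_means().pivot(index="site", columns="time",
                                     values="value").to_numpy()
naive = ps.avg_residual_corr(grid).average
print(f"true synchrony rho                  = {process.error.rho:.2f}")
print(f"posterior mean rho (state-space)    = {result.summary['rho']['mean']:.3f}")
print(f"naive residual-correlation estimate = {naive:.3f}")
print()
print("posterior-mean residual correlation matrix (supports negative synchrony):")
print(np.round(ps.residual_corr_matrix(result.residual_means()), 2))
print()
print("The state-space interval covers the truth while the naive estimate")
print("is strongly attenuated by the sampling error it ignores.")
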