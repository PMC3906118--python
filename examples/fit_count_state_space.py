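"""Joint estimation of detection, overdispersion and synchrony from counts.

Simulates a transect-count survey with imperfect detection (p = 0.6),
negative-binomial overdispersion in availability (theta = 5) and GICC
process errors (per-site variances, shared fraction 0.7), then fits the
count state-space model.  Availability is marginalized analytically through
the binomial-thinning closure of the negative binomial, so no discrete
latent block is sampled.
"""

import numpy as np

import popsync as ps

n_sites, n_times = 3, 16
process = ps.ProcessSpec(alpha=0.8, beta=-0.4,
                         error=ps.GICCError(np.full(n_sites, 0.15), rho_prime=0.7))
design = ps.SimDesign(n_sites=n_sites, n_times=n_times,
                      sessions_per_site_time=2, replicates_per_session=3, seed=21)
states = ps.simulate_states(design, process)
sampling = ps.CountSampling(theta=5.0, p=0.6, b=0.0, sigma2_gamma=0.01)
panel = ps.simulate_count_sampling(states, design, sampling,
                                   rng=np.random.default_rng(22))
print(f"simulated {len(panel.data)} transect counts, "
      f"mean {panel.data.value.mean():.1f} animals per count")

spec = ps.CountSSMSpec(panel)
result = ps.fit(spec, ps.MCMCConfig(n_chains=2, n_iter=6000, n_burnin=2500,
                                    thin=3, seed=23), save_latents=False)
print(result.summary.table.round(3).to_string(index=False))
print()
print("truth: rho_prime 0.7, theta 5.0, detection 0.6 at every site,")
print("per-site process variance 0.15, alpha 0.8, beta -0.4.")
print("p_mean[site] rows show detection recovered from count replication")
print("alone (N-mixture logic); rho_prime is the shared fraction of each")
print("site's process variance, i.e. the average synchrony.  The covered")
print("distance is constant here, so the coefficient b is unidentified and")
print("simply returns its wide prior -- expected, not a failure.")
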