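# popsync

Estimating the **spatial synchrony** of population dynamics — the zero-lag
correlation between the fluctuations of spatially disjoint populations —
while properly separating **process variation** (true year-to-year change)
from **sampling error** (the noise in abundance estimates).

Abundance data are almost never censuses. When each site-year estimate
carries independent additive noise of variance *v*<sub>s</sub>, the usual
Pearson correlation of two observed log-abundance series is attenuated:

E[*r̂*] ≈ ρ · (1 − *v*<sub>s</sub>/*V*),

where *V* is the total temporal variance (process + sampling). A survey in
which half the observed variance is sampling noise therefore reports only
half the true synchrony — enough to turn a strong Moran effect (climate
forcing shared across sites) into an apparently weak one, and to make a
metapopulation look safer than it is.

`popsync` provides the two remedies, plus the machinery to study the bias
itself:

1. **Analytic correction** (known sampling variance):
   *r̂*<sub>corr</sub> = cov(*y*, *y*′) / √((*V̂* − *v*<sub>s</sub>)(*V̂*′ − *v*<sub>s</sub>)).
2. **Bayesian state-space models** (sampling variance assigned or jointly
   estimated). The state process is a Gompertz model on the log scale,
   *x*<sub>*i*,*t*</sub> = *x*<sub>*i*,*t*−1</sub> + α + β·*x*<sub>*i*,*t*−1</sub> + ε<sub>*i*,*t*</sub>,
   with the process errors ε split into shared and unshared components:
   - **ICC** form (equal site variances): ε<sub>*ij*</sub> = *c*<sub>*j*</sub> + *d*<sub>*ij*</sub>,
     with synchrony ρ = σ²<sub>c</sub>/(σ²<sub>c</sub>+σ²<sub>d</sub>);
   - **GICC** form (site-specific variances σ²<sub>*i*</sub>): a shared
     fraction ρ′ of each site's residual variance.

   Two observation processes are supported: Gaussian log-abundance
   estimates with assigned sampling SDs and session random effects
   (fishery CPUE style), and replicated transect counts with imperfect
   detection — availability is negative-binomial with mean λ and variance
   λ + λ²/θ, thinned by Binomial(*N*, *p*<sub>*ij*</sub>), with a
   log covered-distance covariate. The thinned negative binomial is again
   negative binomial (same θ, mean *p*λ), so the discrete availability is
   marginalized exactly.
3. **Simulators and bias experiments**: a superpopulation simulator for
   both observation processes, and the Monte-Carlo "what-if" experiment
   measuring how much bias survives when *N*<sub>K</sub> replicate
   estimates are averaged before a naive residual-correlation analysis.

## Worked example

```python
import numpy as np
import popsync as ps

# truth: strong synchrony (rho = 0.86), noisy survey (sigma2_s = 0.165/session)
process = ps.ProcessSpec(alpha=0.25, beta=-0.26,
                         error=ps.ICCError(sigma2_c=0.0344, sigma2_d=0.0056))
design = ps.SimDesign(n_sites=3, n_times=24, sessions_per_site_time=4, seed=11)
states = ps.simulate_states(design, process)
panel = ps.simulate_gaussian_sampling(
    states, design, ps.GaussianSampling(sigma2_s=0.165, sigma2_gamma=0.007),
    rng=np.random.default_rng(12))

result = ps.fit(ps.GaussianSSMSpec(panel),
                ps.MCMCConfig(n_chains=3, n_iter=6000, n_burnin=2500, thin=3, seed=13))
print(result.summary.table.round(3))
```

prints (abridged):

```
        name   mean    sd  ci2.5  ci97.5  rhat
        beta -0.503 0.216 -0.996  -0.166 1.001
         rho  0.886 0.110  0.569   0.990 1.001
```

while the naive residual-correlation estimate on the same panel is **0.41**
— less than half the truth. The state-space posterior (ρ = 0.89 ± 0.11)
covers the generating value 0.86 because the model knows each record's
sampling SD and attributes the right share of the observed variance to
noise. `examples/` contains this script and three more (attenuation
correction, count-model fitting with detection, the replicate-averaging
bias experiment), each printing a short interpretation of its numbers.

A thin CLI wraps the same functions:

```bash
popsync simulate --config sim.yaml --seed 4 --out panel.csv
popsync correct --input panel.csv --sampling-var 0.05
popsync fit-gaussian --input panel.csv --seed 5 --out summary.csv
popsync whatif --kind fish --seed 3 --out bias.csv
```

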