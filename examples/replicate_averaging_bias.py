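"""How much bias survives averaging N_K replicate abundance estimates?

Runs the fish-protocol Monte-Carlo experiment: simulate true Gompertz
dynamics at the fitted study conditions, observe each site-year with N_K
noisy log-abundance estimates, average them, fit a Gompertz model per site
and correlate the residuals.  The printed table shows the naive synchrony
estimate climbing toward the gold standard (0.86) only slowly with N_K:
with the 3 replicates typical of field studies, roughly 60% of the
synchrony is still missing, and density dependence (beta) is overestimated.
"""

import popsync as ps
from popsync import whatif

result = ps.run_whatif_gaussian(
    whatif.FISH_PROCESS, whatif.FISH_SAMPLING_VARIANCE,
    ps.SimDesign(n_sites=3, n_times=24, seed=None),
    nk_list=[1, 3, 10, 50], n_m=500, seed=31)

table = ps.bias_report(result)
print(table.round(3).to_string(index=False))
print()
print(f"gold-standard synchrony (state-space estimate used as truth): "
      f"{result.rho_gold:.2f}")
print("mean_r: Monte-Carlo mean of the average residual correlation;")
print("pct_underestimation = 100 * (1 - mean_r / gold standard).")
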