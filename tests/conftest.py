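import numpy as np
import pandas as pd
import pytest

import popsync as ps


@pytest.fixture
def fish_process() -> ps.ProcessSpec:
    """Gompertz + ICC errors at the fish-style study conditions."""
    return ps.ProcessSpec(alpha=0.25, beta=-0.26,
                          error=ps.ICCError(sigma2_c=0.04 * 0.86, sigma2_d=0.04 * 0.14))


@pytest.fixture
def toy_panel() -> ps.ObservationPanel:
    """2 sites x 3 times, one log-abundance record each."""
    df = pd.DataFrame({
        "site": ["a", "a", "a", "b", "b", "b"],
        "time": [1, 2, 3, 1, 2, 3],
        "session": 1,
        "replicate": 1,
        "value": [1.0, 1.2, 0.8, 0.9, 1.1, 1.0],
        "kind": "log_abundance",
        "sampling_sd": 0.3,
        "log_distance": np.nan,
    })
    return ps.ObservationPanel(df)


def make_gaussian_panel(n_sites=3, n_times=24, sessions=3, sigma2_s=0.165,
                        sigma2_gamma=0.007, seed=0, process=None):
    """Simulate a fish-style panel with its generating states."""
    rng = np.random.default_rng(seed)
    design = ps.SimDesign(n_sites=n_sites, n_times=n_times,
                          sessions_per_site_time=sessions, seed=None)
    if process is None:
        process = ps.ProcessSpec(alpha=0.25, beta=-0.26,
                                 error=ps.ICCError(0.04 * 0.86, 0.04 * 0.14))
    states = ps.simulate_states(design, process, rng=rng)
    pan = ps.simulate_gaussian_sampling(
        states, design, ps.GaussianSampling(sigma2_s, sigma2_gamma), rng=rng)
    return pan, states


def make_count_panel(n_sites=3, n_times=12, sessions=2, replicates=3, seed=0,
                     theta=5.0, p=0.6, sigma2_gamma=0.01, poisson_limit=False,
                     process=None):
    """Simulate a cat-style replicated count panel with its states."""
    rng = np.random.default_rng(seed)
    design = ps.SimDesign(n_sites=n_sites, n_times=n_times,
                          sessions_per_site_time=sessions,
                          replicates_per_session=replicates, seed=None)
    if process is None:
        process = ps.ProcessSpec(alpha=0.8, beta=-0.4,
                                 error=ps.GICCError(np.full(n_sites, 0.15), 0.7))
    states = ps.simulate_states(design, process, rng=rng)
    sampling = ps.CountSampling(theta=theta, p=p, b=0.0,
                                sigma2_gamma=sigma2_gamma,
                                poisson_limit=poisson_limit)
    pan = ps.simulate_count_sampling(states, design, sampling, rng=rng)
    return pan, states
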