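import numpy as np
import pytest

import wetland_svc as w


@pytest.fixture(scope="session")
def small_sites():
    """A 20x20 synthetic site table with known truth (session-cached)."""
    cfg = w.SimulationConfig(
        n_sites_x=20, n_sites_y=20, n_regions=4, seed=11,
        true_alpha=(1.0, -0.5, 0.3, 0.0),
        true_surface=np.array([[-0.5, 0.0, 0.5]]),
        tau2_psi=0.1,
    )
    return w.simulate_sites(cfg)


@pytest.fixture(scope="session")
def quick_chain(small_sites):
    """A short but adapted chain on the small synthetic fit."""
    sites, _ = small_sites
    spec = w.build_model_spec(sites, k1=1, k2=1)
    chain = w.run_sampler(
        spec, w.SamplerConfig(n_iterations=2400, n_burnin=1200, seed=5))
    return spec, chain
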