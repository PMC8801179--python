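import logging

import numpy as np
import pytest

import bayescr as b

logging.getLogger("bayescr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def coarse_survey():
    """Small no-sex survey used by several sampler/diagnostics tests."""
    spec = b.ModelSpec("leopard", "shared", "fixed_zero", "fixed", 0.75)
    pars = b.Parameters(1.0, 1.0, 0.05, 0.0, theta=0.75)
    traps, mask, enc, truth = b.make_lmnp_fixture(
        seed=42, pixel_km=2.0, buffer_km=8.0, k_occasions=20,
        density_per_100km2=8.0, params=pars, spec=spec,
    )
    return spec, pars, traps, mask, enc, truth


@pytest.fixture(scope="session")
def coarse_chain(coarse_survey):
    spec, pars, traps, mask, enc, truth = coarse_survey
    cfg = b.McmcConfig(n_iter=1500, burn_in=600, n_chains=2, nz=200, seed=11)
    chains = b.run_mcmc(spec, enc, traps, mask, cfg)
    return chains


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
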