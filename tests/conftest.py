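import warnings

import pytest

from enhdyn.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down landscape for cheap integration-style unit tests."""
    return SimulationConfig(
        seed=11,
        n_promoters=80,
        n_enhancers=60,
        n_negative_controls=40,
        pairs_per_anchor=600.0,
        n_planted_interactions=30,
        n_gwas_snps=30,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(small_config)
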