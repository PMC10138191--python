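import pytest

from tfbsmeth import SimulationConfig, simulate_bundle, write_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_sites=300, n_background_probes=100, missing_rate=0.01, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One seeded scaled-down study bundle shared across tests."""
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def bundle_paths(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_bundle, outdir)
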