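import pytest

from editlink.discovery import extract_observations, pair_sites
from editlink.sim import SimConfig, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """Default synthetic dataset: 2 genes, 60 adjacent pairs, coverage 200."""
    return simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def dataset_paths(dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return write_dataset(dataset, str(outdir))


@pytest.fixture(scope="session")
def discovered_pes(dataset, dataset_paths):
    obs = extract_observations(dataset_paths["sam"], dataset.sites)
    return pair_sites(obs, dataset.models)
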