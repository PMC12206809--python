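import pytest

from famdiv.simulate import SimulationConfig, simulate_bundle, write_bundle

#: fixed seed for the shared synthetic study bundle
SEED = 11


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=SEED)


@pytest.fixture(scope="session")
def bundle(sim_config):
    """(genome, models, sites, samples, ct, truth) for the default conditions."""
    return simulate_bundle(sim_config)


@pytest.fixture(scope="session")
def bundle_dir(sim_config, tmp_path_factory):
    """The same bundle written to disk as FASTA/GFF3/VCF/TSV/JSON."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(sim_config, outdir)
    return paths
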