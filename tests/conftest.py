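import pytest

from alienscan import synthetic_data as sd


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic genome (1000 genes, 5% planted aliens),
    shared across tests that only read from it."""
    return sd.simulate(sd.SimulationScenario())


@pytest.fixture(scope="session")
def default_bundle_dir(default_bundle, tmp_path_factory):
    """The default bundle written out in every pipeline input format."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = sd.write_bundle(default_bundle, outdir)
    return paths
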