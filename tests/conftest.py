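import pytest
from hypothesis import settings

from metabarcode.synthetic import NetworkPlan, gen_network, make_pipeline_fixtures

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_network():
    """Connected 120-node metabolite-protein network, fixed seed."""
    return gen_network(NetworkPlan(seed=7))


@pytest.fixture(scope="session")
def pipeline_fixture_dir(tmp_path_factory):
    """One consistent set of pipeline input files."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_pipeline_fixtures(out, seed=3)
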