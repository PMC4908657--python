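import pytest

from n3pas.extraction import PolyASite
from n3pas.pipeline import run_all
from n3pas.simulate import ScenarioConfig, generate


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic scenario, shared across test modules."""
    return generate(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def default_results(default_fixture):
    """Full pipeline output on the default scenario."""
    fx = default_fixture
    sites = [PolyASite(*r) for r in fx.site_records()]
    return run_all(genes=fx.genes, genome=fx.genome, sites=sites, tes=fx.tes)


@pytest.fixture(scope="session")
def truth_by_pos(default_fixture):
    return default_fixture.truth_by_pos()
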