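import pytest

from shellcaps import GeneratorConfig, default_marker_model, make_alleles, make_panel

DURA_CONTEXT = "GGACTGCTGAAGAAAGCTTAT"
PISIFERA_CONTEXT = "GGACTGCTGAAGAATGCTTAT"


@pytest.fixture(scope="session")
def cfg():
    """Default generator configuration (seeded)."""
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def alleles(cfg):
    return make_alleles(cfg)


@pytest.fixture(scope="session")
def panel(cfg):
    return make_panel(cfg)


@pytest.fixture(scope="session")
def marker_model(cfg):
    return default_marker_model(cfg)
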