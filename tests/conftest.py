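import pytest

from nanodos import dielectric as dl
from nanodos.elastic import ElasticModel
from nanodos.electron import ElectronTables


@pytest.fixture(scope="session")
def model() -> dl.ELFModel:
    return dl.load_default_model()


@pytest.fixture(scope="session")
def xs_table(model) -> dl.CrossSectionTable:
    return dl.CrossSectionTable(model)


@pytest.fixture(scope="session")
def elastic_model() -> ElasticModel:
    return ElasticModel()


@pytest.fixture(scope="session")
def etables(xs_table, elastic_model) -> ElectronTables:
    return ElectronTables(xs_table, elastic_model)
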