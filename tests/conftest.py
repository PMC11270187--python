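import pytest

from abgraft.germline import load_default_library
from abgraft.numbering import number_sequence
from abgraft.synthetic import full_length_chain


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def by_gene(library):
    return {e.gene_name: e for e in library}


@pytest.fixture(scope="session")
def human_heavy(library):
    return [e for e in library if e.chain_class == "heavy" and e.gene_name != "IGHV2-9"]


@pytest.fixture(scope="session")
def human_kappa(library):
    return [e for e in library if e.chain_class == "kappa" and e.gene_name != "IGKV9-124"]


@pytest.fixture(scope="session")
def parental_heavy(by_gene):
    """Full-length murine-derived parental heavy chain (V gene + J FR4)."""
    return full_length_chain(by_gene["IGHV2-9"])


@pytest.fixture(scope="session")
def parental_light(by_gene):
    return full_length_chain(by_gene["IGKV9-124"])


@pytest.fixture(scope="session")
def parental_heavy_kabat(parental_heavy):
    return number_sequence(parental_heavy, "kabat")


@pytest.fixture(scope="session")
def parental_light_kabat(parental_light):
    return number_sequence(parental_light, "kabat")


@pytest.fixture(scope="session")
def parental_heavy_imgt(parental_heavy):
    return number_sequence(parental_heavy, "imgt")


@pytest.fixture(scope="session")
def parental_light_imgt(parental_light):
    return number_sequence(parental_light, "imgt")
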