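import pytest

from plastidkit import datasets


@pytest.fixture(scope="session")
def mutation_table():
    return datasets.load_mutation_table()


@pytest.fixture(scope="session")
def genotype_table():
    return datasets.load_genotype_table()


@pytest.fixture(scope="session")
def primer_table():
    return datasets.load_primer_table()
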