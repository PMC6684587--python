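import pytest

import stresscorr as sc


@pytest.fixture(scope="session")
def raw_table():
    return sc.load_builtin("strains95")


@pytest.fixture(scope="session")
def table(raw_table):
    return sc.transform(raw_table)


@pytest.fixture(scope="session")
def asco(table):
    return sc.subset(table, phylum="A")


@pytest.fixture(scope="session")
def basidio(table):
    return sc.subset(table, phylum="B")
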