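import pytest

from hydroq.data_model import load_fixture


@pytest.fixture(scope="session")
def registry():
    return load_fixture("registry")


@pytest.fixture(scope="session")
def profiles():
    return load_fixture("profiles")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture(scope="session")
def elements(table2, table3):
    return table2 + table3


@pytest.fixture(scope="session")
def survey(table1, elements):
    return table1 + elements
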