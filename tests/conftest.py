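import pytest

from orcx import fixtures


@pytest.fixture(scope="session")
def m32():
    return fixtures.load_fixture("M32")


@pytest.fixture(scope="session")
def m33a():
    return fixtures.load_fixture("M33A")


@pytest.fixture(scope="session")
def m33b():
    return fixtures.load_fixture("M33B")


@pytest.fixture(scope="session")
def m33c():
    return fixtures.load_fixture("M33C")


@pytest.fixture(scope="session")
def m34():
    return fixtures.load_fixture("M34")


@pytest.fixture(scope="session")
def m35():
    return fixtures.load_fixture("M35")
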