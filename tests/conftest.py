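import pytest

from acetotrace import datasets


@pytest.fixture(scope="session")
def registry():
    return datasets.default_registry()


@pytest.fixture(scope="session")
def reference_rates():
    return datasets.reference_rates()


@pytest.fixture(scope="session")
def reference_yields():
    return datasets.reference_yields()


@pytest.fixture(scope="session")
def reference_nmr():
    return datasets.reference_nmr()


@pytest.fixture(scope="session")
def chemostat_config():
    return datasets.default_config()
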