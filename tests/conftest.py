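import pytest

from brachyaudit.tg43 import load_source


@pytest.fixture(scope="session")
def toy_source():
    return load_source("toy")


@pytest.fixture(scope="session")
def ir_source():
    return load_source("ir192_generic")


@pytest.fixture(scope="session")
def co_source():
    return load_source("co60_generic")
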