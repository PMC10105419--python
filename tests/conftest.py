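import pytest

from lanmine.simulate import load_fixture


@pytest.fixture(scope="session")
def alpha():
    return load_fixture("archalan_alpha")


@pytest.fixture(scope="session")
def beta():
    return load_fixture("archalan_beta")
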