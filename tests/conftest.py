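import pytest

from aquarisk import builtin_default_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_default_registry()


@pytest.fixture(scope="session")
def arsenic(registry):
    return registry["arsenic"]
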