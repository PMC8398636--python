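import pytest

from linexnet import default_ruleset


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def registry(rules):
    return rules.registry
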