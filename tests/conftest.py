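import pytest

from oncocea import builtin_config, run_pipeline


@pytest.fixture(scope="session")
def china_config():
    return builtin_config("china")


@pytest.fixture(scope="session")
def us_config():
    return builtin_config("us")


@pytest.fixture(scope="session")
def china_ps(china_config):
    return run_pipeline(china_config, engine="ps")


@pytest.fixture(scope="session")
def us_ps(us_config):
    return run_pipeline(us_config, engine="ps")


@pytest.fixture(scope="session")
def china_markov(china_config):
    return run_pipeline(china_config, engine="markov")
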