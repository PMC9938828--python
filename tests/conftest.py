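import pytest
from hypothesis import settings

from ptew.config import load_config
from ptew.synth import GeneratorConfig, generate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def metals(config):
    return config.metals


@pytest.fixture(scope="session")
def profiles(config):
    return config.profiles


@pytest.fixture(scope="session")
def study(config):
    return config.study


@pytest.fixture(scope="session")
def samples():
    """One fixed draw of the default 45+45 seasonal design."""
    return generate(GeneratorConfig(seed=2021))
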