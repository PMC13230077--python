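import pytest

from acscea import (AnalysisSettings, gen_synthetic_life_table, load_config)


@pytest.fixture(scope="session")
def default_model():
    """Packaged base-case parameters and settings."""
    return load_config()


@pytest.fixture(scope="session")
def params(default_model):
    return default_model[0]


@pytest.fixture(scope="session")
def settings(default_model):
    return default_model[1]


@pytest.fixture(scope="session")
def lt():
    """Default synthetic Gompertz-Makeham life table, ages 62-100."""
    return gen_synthetic_life_table()
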