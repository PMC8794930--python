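import pytest

from strokecea import (
    default_parameters,
    synthetic_life_table,
    synthetic_us_life_table,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    """Gompertz-Makeham synthetic table, ages 50-110."""
    return synthetic_life_table()


@pytest.fixture(scope="session")
def us_life_table():
    """Synthetic stand-in for a recent US unisex annual period life table."""
    return synthetic_us_life_table()
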