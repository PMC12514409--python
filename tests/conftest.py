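import pytest

from colocea import basecase, default_life_table, run_comparison
from colocea.table3 import reference_comparison


@pytest.fixture(scope="session")
def config():
    return basecase()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_comparison(config, life_table):
    """Full five-strategy comparison under base-case parameters."""
    return run_comparison(config, life_table)


@pytest.fixture(scope="session")
def ref_comparison():
    """Comparison built from the bundled reference outcome totals."""
    return reference_comparison()
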