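import pytest

from pdcea.parameters import published_defaults
from pdcea.outcomes import run_base_case


@pytest.fixture
def defaults():
    """A fresh copy of the published parameter inventory."""
    return published_defaults()


@pytest.fixture(scope="session")
def base_case():
    """(conventional, exenatide, incremental) under published defaults."""
    return run_base_case(published_defaults())
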