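import pytest

from syntherm import load_default_library
from syntherm.scenarios import reference_conditions


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture()
def screening_conditions():
    """Reference screening conditions at pH 5 (1 mM metabolites, stated pressures)."""
    return reference_conditions(pH=5.0)
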