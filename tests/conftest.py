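import pytest

from famchar.synthetic_data import simulate_family
from famchar.table1 import table1_profiles


@pytest.fixture(scope="session")
def family_bundle():
    """One synthetic family genome shared by recovery tests (fixed seed)."""
    return simulate_family(101)


@pytest.fixture(scope="session")
def table1():
    """Packaged descriptor table as (profiles, id->group)."""
    return table1_profiles()
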