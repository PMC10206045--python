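import pytest

from wrkykit import fixtures as fx
from wrkykit import simulate as sim


@pytest.fixture(scope="session")
def table1():
    return fx.load_table1()


@pytest.fixture(scope="session")
def candidate_lists():
    return fx.load_candidate_lists()


@pytest.fixture(scope="session")
def reassignment_map():
    return fx.load_reassignment_map()


@pytest.fixture(scope="session")
def small_proteome():
    """Two clean planted proteins per subgroup class, fixed seed."""
    return sim.gen_wrky_proteome(2, seed=42)
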