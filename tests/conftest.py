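import pytest

from fiberextract.scenarios import table1_case
from fiberextract.solver import Resolution, solve_steady


@pytest.fixture(scope="session")
def coarse_res():
    """Resolution used for fast full-problem solves in tests."""
    return Resolution(nr=(24, 12, 24), nz=96)


@pytest.fixture(scope="session")
def ip_tube_case():
    return table1_case("IP", "feed_in_tube")


@pytest.fixture(scope="session")
def ip_tube_field(ip_tube_case, coarse_res):
    return solve_steady(ip_tube_case.problem, resolution=coarse_res)
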