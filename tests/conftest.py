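import pytest

from chlorofba.fixture import build_leaf_fixture
from chlorofba.scenarios import case1


@pytest.fixture(scope="session")
def leaf_model():
    return build_leaf_fixture()


@pytest.fixture(scope="session")
def case1_solution(leaf_model):
    sol = case1().solve(leaf_model)
    assert sol.status == "optimal"
    return sol
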