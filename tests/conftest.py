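import pytest

from genovault import container as cont
from genovault import fixtures as fx
from genovault import policy as pol


@pytest.fixture
def empty_container(tmp_path):
    return cont.create_container(tmp_path / "box")


@pytest.fixture
def small_container(tmp_path):
    """2 groups x 2 datasets x 1 AU x 1 block, all-permit policies."""
    spec = fx.FixtureSpec(seed=7)
    return fx.generate_fixture(spec, tmp_path / "fixture")


@pytest.fixture
def worked_example():
    return pol.build_worked_example()
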