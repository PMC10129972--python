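import pytest
from hypothesis import settings

from phylocover import fixtures

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fx():
    return fixtures()


@pytest.fixture(scope="session")
def ex45_cover(fx):
    return fx["ex45_cover"]


@pytest.fixture(scope="session")
def fig3_cover(fx):
    return fx["fig3_cover"]


@pytest.fixture(scope="session")
def fig2_gadget(fx):
    return fx["fig2_gadget"]


@pytest.fixture(scope="session")
def zigzag(fx):
    return fx["zigzag_network"]


@pytest.fixture(scope="session")
def min_reticulation(fx):
    return fx["min_reticulation"]


@pytest.fixture(scope="session")
def cherry_tree():
    from phylocover import PhyloNetwork
    return PhyloNetwork([("r", "a"), ("r", "b")], {"a": 1, "b": 2})
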