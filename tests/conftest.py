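import pytest

from pdsets import branching_profile, ultrametric_heights
from pdsets.fixtures import tree_T1, tree_T2, tree_T3, tree_mammal_P


@pytest.fixture(scope="session")
def t1():
    return tree_T1()


@pytest.fixture(scope="session")
def t1_heights(t1):
    return ultrametric_heights(t1)


@pytest.fixture(scope="session")
def t1_profile(t1, t1_heights):
    return branching_profile(t1, t1_heights)


@pytest.fixture(scope="session")
def t2():
    return tree_T2()


@pytest.fixture(scope="session")
def t2_heights(t2):
    return ultrametric_heights(t2)


@pytest.fixture(scope="session")
def t3():
    return tree_T3()


@pytest.fixture(scope="session")
def t3_heights(t3):
    return ultrametric_heights(t3)


@pytest.fixture(scope="session")
def mammal():
    return tree_mammal_P()
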