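import pytest

from wmtime import DEFAULT_PARAMS, build_exp1_design, build_exp2_design, simulate_accuracy


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def exp1_small():
    return build_exp1_design(n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def exp2a_small():
    return build_exp2_design("a", n_subjects=3, seed=12)


@pytest.fixture(scope="session")
def exp2b_small():
    return build_exp2_design("b", n_subjects=6, seed=13)


@pytest.fixture(scope="session")
def exp2b_data(exp2b_small):
    return simulate_accuracy(exp2b_small, DEFAULT_PARAMS, seed=21)
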