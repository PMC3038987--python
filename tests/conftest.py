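import numpy as np
import pytest

from polcomp import toy_locus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_gene():
    return toy_locus("single_gene", lam=0.1)


@pytest.fixture
def convergent_pair():
    return toy_locus("convergent_pair", lam=0.1)


@pytest.fixture
def locus1():
    return toy_locus("locus1_fixture")


@pytest.fixture
def locus2():
    return toy_locus("locus2_fixture")


@pytest.fixture
def locus3():
    return toy_locus("locus3_fixture")
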