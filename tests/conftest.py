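import numpy as np
import pytest

from genepaf.fixtures import correlated_pair, independent_trio, lung_gwas_variants


@pytest.fixture
def lung_variants():
    return lung_gwas_variants()


@pytest.fixture
def trio():
    return independent_trio()


@pytest.fixture
def ld_pair():
    return correlated_pair()


@pytest.fixture
def rng():
    return np.random.default_rng(20180352)
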