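import numpy as np
import pytest

import cladecal as cc
from cladecal.trees import TimeTree


@pytest.fixture
def two_tip():
    return TimeTree(["A", "B"], [2, 2, -1], [0.0, 0.0, 100.0])


@pytest.fixture
def three_tip():
    # ((A,B),C) with the cherry at 10 Ma and the root at 25 Ma
    return TimeTree(["A", "B", "C"], [3, 3, 4, 4, -1], [0, 0, 0, 10.0, 25.0])


@pytest.fixture
def six_tip():
    return TimeTree.from_newick(
        "(((A:20,B:20):30,(C:25,D:25):25):50,(E:60,F:60):40):0;"
    )


@pytest.fixture
def teleost_bd():
    return cc.BDParams(
        net_diversification=(0.041, 0.081),
        turnover=(0.0011, 0.37),
        sampling_rate=(0.0066, 0.01806),
    )


@pytest.fixture
def gtr_model():
    return cc.SubstModel(
        exchangeabilities=(1.2, 2.0, 0.8, 1.1, 2.5, 1.0),
        base_frequencies=(0.3, 0.2, 0.25, 0.25),
        gamma_shape=0.5,
        n_categories=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
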