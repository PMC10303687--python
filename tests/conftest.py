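import dendropy
import numpy as np
import pytest

from paleoaffinity.alignment import Alignment
from paleoaffinity.substitution import AMINO_ACIDS, jtt_model


@pytest.fixture(scope="session")
def jtt():
    return jtt_model()


@pytest.fixture
def four_leaf_tree():
    nwk = "((L1:0.1,L2:0.3)N2:0.2,(L3:0.15,L4:0.25)N3:0.05)N1;"
    return dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)


@pytest.fixture
def three_leaf_tree():
    nwk = "(L1:0.2,L2:0.4,L3:0.1)N1;"
    return dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)


def random_alignment(ids, n_sites, seed):
    rng = np.random.default_rng(seed)
    return Alignment(
        [(i, "".join(rng.choice(list(AMINO_ACIDS), n_sites))) for i in ids]
    )
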