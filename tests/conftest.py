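import numpy as np
import pytest

from hgtscreen.alignment import Alignment
from hgtscreen.simulate import SimConfig, evolve_alignment, make_hgt_benchmark
from hgtscreen.substmodels import SubstitutionModel
from hgtscreen.tree import Tree


@pytest.fixture(scope="session")
def lg():
    return SubstitutionModel("LG")


@pytest.fixture(scope="session")
def lg_g():
    return SubstitutionModel("LG", gamma_shape=0.8)


@pytest.fixture(scope="session")
def six_taxon_tree():
    return Tree.from_newick(
        "((a:0.15,b:0.3):0.12,(c:0.25,d:0.1):0.18,(e:0.2,f:0.35):0.1);"
    )


@pytest.fixture(scope="session")
def six_taxon_alignment(six_taxon_tree, lg_g):
    return evolve_alignment(six_taxon_tree, lg_g, 500, seed=42)


@pytest.fixture(scope="session")
def hgt_benchmark():
    return make_hgt_benchmark(SimConfig(hgt=True, seed=3))


@pytest.fixture(scope="session")
def vertical_benchmark():
    return make_hgt_benchmark(SimConfig(hgt=False, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_alignment():
    return Alignment(["s1", "s2", "s3", "s4"], ["ARND", "ARNE", "A-ND", "XRND"])
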