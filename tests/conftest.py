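import numpy as np
import pytest

import urbanphylo as up

#: 3-tip worked tree used for hand-checkable linear algebra throughout
WORKED_NEWICK = "((A:1,B:1):1,C:2);"


def star_newick(n: int, branch: float = 1.0) -> str:
    return "(" + ",".join(f"t{i}:{branch:g}" for i in range(n)) + ");"


def balanced_newick(depth: int, tip_branch: float = 0.1, inner_branch: float = 1.0) -> str:
    """Fully balanced binary tree with 2**depth tips: long internal branches,
    short tip branches, i.e. deep clade structure white noise cannot mimic."""
    counter = [0]

    def build(d: int) -> str:
        if d == 0:
            counter[0] += 1
            return f"t{counter[0]}:{tip_branch:g}"
        return f"({build(d - 1)},{build(d - 1)}):{inner_branch:g}"

    return f"({build(depth - 1)},{build(depth - 1)});"


@pytest.fixture(scope="session")
def worked_tree():
    return up.parse_newick(WORKED_NEWICK)


@pytest.fixture(scope="session")
def worked_cov(worked_tree):
    return up.compute_vcv(worked_tree)


@pytest.fixture(scope="session")
def yule50():
    return up.simulate_yule_tree(50, birth_rate=1.0, seed=20)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-species synthetic survey shared by the pipeline tests."""
    return up.simulate_dataset(up.SimulationConfig(n_species=40, seed=9))
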