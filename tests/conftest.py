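import numpy as np
import pytest

from ithmix.likelihood import SampleData, SpmRecord
from ithmix.simulate import SimConfig, draw_ith, draw_reads, truth_to_sample
from ithmix.trees import CopyState, enumerate_trees


@pytest.fixture(scope="session")
def all_trees():
    return enumerate_trees(5)


@pytest.fixture(scope="session")
def branching3(all_trees):
    """The three-subclone branching tree B <- A -> C."""
    for tree in all_trees:
        if tree.n_subclones == 3 and tree.parent == (None, 0, 0):
            return tree
    raise AssertionError("branching tree not enumerated")


@pytest.fixture(scope="session")
def linear3(all_trees):
    for tree in all_trees:
        if tree.n_subclones == 3 and tree.parent == (None, 0, 1):
            return tree
    raise AssertionError("linear tree not enumerated")


def make_sample(rng, n_spms=30, purity=0.8, depth=200, subclone_prev=0.3):
    """A diploid two-cluster sample: half clonal, half at a subclonal prevalence."""
    spms = []
    for i in range(n_spms):
        t = max(int(rng.poisson(depth)), 10)
        prev = 1.0 if i % 2 == 0 else subclone_prev
        p = purity * prev / 2.0
        a = int(rng.binomial(t, p))
        spms.append(SpmRecord(alt_count=a, ref_count=t - a, state=CopyState(1, 1)))
    return SampleData(spms=tuple(spms), purity=purity)


@pytest.fixture
def simulated_sample():
    """One simulated read-count sample with its generating truth."""
    rng = np.random.default_rng(7)
    config = SimConfig(depth_mean=500, n_spms=100)
    truth = draw_ith(config, rng)
    draw_reads(truth, config, rng)
    return truth, truth_to_sample(truth)
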