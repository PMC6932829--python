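import pytest

import cophylo as cp


@pytest.fixture
def ind3():
    return cp.parse_newick("((A,B),C);")


@pytest.fixture
def jane_costs():
    return cp.JANE_DEFAULT_COSTS


def random_bijection_dataset(n_tips: int, pair_seed: int, shuffle_rng):
    """Two independent Yule trees plus a uniform random tip bijection."""
    ind = cp.simulate_host_tree(n_tips, seed=pair_seed)
    dep = cp.simulate_host_tree(n_tips, seed=pair_seed + 1)
    perm = ind.tip_labels[:]
    shuffle_rng.shuffle(perm)
    assoc = cp.AssociationTable.from_pairs(
        list(zip(dep.tip_labels, perm)), dep_tree=dep, ind_tree=ind)
    return ind, dep, assoc
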