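import numpy as np
import pytest

import phylopred as pp


@pytest.fixture
def three_tip():
    """((A:0.5,B:0.5):0.5,C:1); — ultrametric, height 1."""
    return pp.read_newick("((A:0.5,B:0.5):0.5,C:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def brute_force_vcv(tree: "pp.Phylogeny"):
    """Independent oracle: sum branch lengths over explicitly enumerated
    root-to-MRCA paths for every tip pair."""
    dtree = tree.dtree
    leaves = list(dtree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]

    def ancestors(node):
        chain = [node]
        while chain[-1].parent_node is not None:
            chain.append(chain[-1].parent_node)
        return chain  # node ... root

    def path_to_root_length(node):
        total = 0.0
        while node.parent_node is not None:
            total += node.edge.length
            node = node.parent_node
        return total

    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        anc_i = ancestors(leaves[i])
        set_i = set(id(a) for a in anc_i)
        for j in range(n):
            if i == j:
                V[i, i] = path_to_root_length(leaves[i])
                continue
            node = leaves[j]
            while id(node) not in set_i:
                node = node.parent_node
            V[i, j] = path_to_root_length(node)
    return V, labels


def sim_with_retry(cfg: "pp.TreeSimConfig", seed: int) -> "pp.Phylogeny":
    """Deterministically resample until the stopping rule is met (extinction
    can kill whole replicates)."""
    ss = np.random.SeedSequence(seed)
    while True:
        ss_tree, ss = ss.spawn(2)
        try:
            return pp.simulate_tree(cfg, np.random.default_rng(ss_tree))
        except pp.SimulationFailure:
            continue


@pytest.fixture
def random_tree_factory():
    """Simulated trees of modest size for oracle comparisons."""

    def make(n_tips=10, seed=0, ext_rate=0.0):
        cfg = pp.TreeSimConfig(
            mode="taxa", n_extant=n_tips, spec_rate=1.0, ext_rate=ext_rate
        )
        return sim_with_retry(cfg, seed)

    return make
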