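import numpy as np
import pytest

from genechron.reconcile import slice_tree
from genechron.synthetic import simulate_dated_tree
from genechron.trees import DatedTree, GeneTree, TreeNode


@pytest.fixture(scope="session")
def three_leaf_species() -> DatedTree:
    """((A,B),C) with the root at 3 Mya and the AB split at 1 Mya."""
    return DatedTree.from_newick("((A:1.0,B:1.0):2.0,C:3.0);")


@pytest.fixture(scope="session")
def three_leaf_sliced(three_leaf_species):
    return slice_tree(three_leaf_species)


@pytest.fixture(scope="session")
def species_10() -> DatedTree:
    return simulate_dated_tree(10, 1e-3, 4e-4, 3800.0, seed=101)


@pytest.fixture(scope="session")
def species_20() -> DatedTree:
    return simulate_dated_tree(20, 1e-3, 4e-4, 3800.0, seed=202)


def random_gene_tree(rng: np.random.Generator, species_labels,
                     n_leaves: int) -> GeneTree:
    """Random rooted binary gene tree over labels drawn with replacement."""
    labels = [str(rng.choice(species_labels)) for _ in range(n_leaves)]
    nodes = [TreeNode(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    return GeneTree(nodes[0], rooted=True)
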