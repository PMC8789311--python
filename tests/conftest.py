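import numpy as np
import pytest

from argsel.fixtures import toy_block, toy_tree
from argsel.grid import TimeGrid, build_time_grid
from argsel.trees import SiteLabel


@pytest.fixture
def tree4():
    """((A,B):1,(C,D):2) root at 3; leaves 0..3 at time 0."""
    return toy_tree()


@pytest.fixture
def grid4():
    """Hand-checkable 4-point grid {0, 1.5, 2.5, 3.5}."""
    return TimeGrid(points=np.array([0.0, 1.5, 2.5, 3.5]), t_max=3.5)


@pytest.fixture
def site_ab():
    """Derived allele carried by A and B (leaves 0, 1)."""
    return SiteLabel(position=50.0, carriers={0, 1})


@pytest.fixture
def block8():
    """The canonical 8-haplotype x 5-site statistic block."""
    return toy_block()


def random_coalescent_trees(n_trees, seed, n_max=20):
    """Random neutral single-locus coalescent trees via msprime."""
    import msprime

    from argsel.trees import LocalTree

    rng = np.random.default_rng(seed)
    trees = []
    for i in range(n_trees):
        n = int(rng.integers(2, n_max + 1))
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n, ploidy=1)],
            ploidy=2,
            population_size=10_000,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        trees.append(LocalTree.from_tskit(ts.first(), interval=(0.0, 1.0)))
    return trees


def brute_force_counts(tree, t):
    """Oracle: count branches whose [child_time, parent_time) contains t."""
    total = 0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        if tree.time[v] <= t < tree.time[p]:
            total += 1
    return max(total, 1)


def brute_force_classified(tree, mutation_node, t):
    """Oracle: (anc, der) by explicit branch-interval enumeration."""
    descend = set()
    stack = [mutation_node]
    children = tree.children()
    while stack:
        v = stack.pop()
        descend.add(v)
        stack.extend(children[v])
    total = der = 0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        if tree.time[v] <= t < tree.time[p]:
            total += 1
            if v in descend:
                der += 1
    total = max(total, 1)
    return total - der, der
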