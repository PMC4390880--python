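import numpy as np
import pytest

from arcogkit.tree_io import CladeMap, Node, RootedTree, parse_newick


@pytest.fixture
def worked_tree() -> RootedTree:
    """((A:1,B:1):1,C:3); — the small hand-checked weighting example."""
    return parse_newick("((A:1,B:1):1,C:3);")


@pytest.fixture
def ab_c_clades() -> CladeMap:
    return CladeMap({"A": "left", "B": "left", "C": "right"})


def random_rooted_tree(
    rng: np.random.Generator,
    n_leaves: int,
    labels=None,
    bl_mean: float = 0.5,
    zero_prob: float = 0.0,
) -> RootedTree:
    """Random binary rooted tree via sequential pairwise joins."""
    if labels is None:
        labels = [f"L{i}" for i in range(n_leaves)]

    def draw_length() -> float:
        if zero_prob and rng.random() < zero_prob:
            return 0.0
        return float(rng.exponential(bl_mean))

    pool = [Node(label=lbl, length=draw_length()) for lbl in labels]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(j)
        a = pool.pop(i)
        parent = Node(length=draw_length())
        parent.add_child(a)
        parent.add_child(b)
        pool.append(parent)
    pool[0].length = 0.0
    return RootedTree(pool[0])
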