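import numpy as np
import pytest

from kdphylo.cognates import CognateMatrix
from kdphylo.phylo import TimeTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    # root at 2000 BP, inner node at 1000 BP, tips contemporaneous
    return TimeTree([-1, 0, 0, 1, 1], [2000.0, 1000.0, 0.0, 0.0, 0.0],
                    [None, None, "C", "A", "B"])


@pytest.fixture
def toy_matrix():
    cells = np.array([[1, 0, 1, 0],
                      [1, 0, 0, 1],
                      [0, 1, -1, -1]], dtype=np.int8)
    return CognateMatrix(["X", "Y", "Z"],
                         [("i1", "a"), ("i1", "b"), ("i2", "a"), ("i2", "b")],
                         cells)


def random_time_tree(rng, n_tips, height=1.0, prefix="t"):
    """Random ultrametric topology via sequential coalescent joins."""
    labels = [f"{prefix}{i}" for i in range(n_tips)]
    parent = [-1] * (2 * n_tips - 1)
    ages = [0.0] * (2 * n_tips - 1)
    labs = labels + [None] * (n_tips - 1)
    nodes = list(range(n_tips))
    t = 0.0
    nxt = n_tips
    while len(nodes) > 1:
        t += rng.exponential(height / n_tips)
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[i], nodes[j]
        parent[a] = parent[b] = nxt
        ages[nxt] = t
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    return TimeTree(parent, ages, labs)
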