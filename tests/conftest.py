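import numpy as np
import pytest

import dolloml as dm


@pytest.fixture(scope="session")
def quartet():
    """((A,B),(C,D)) with unit branch lengths; post-order ids
    A=0 B=1 AB=2 C=3 D=4 CD=5 root=6."""
    return dm.parse_newick("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")


@pytest.fixture(scope="session")
def guide57():
    """The default 57-tip nested-radiation guide tree."""
    return dm.guide_tree(57, seed=2024)


def random_tree(rng: np.random.Generator, n_tips: int) -> "dm.RootedTree":
    """Random bifurcating tree with random branch lengths (for tests)."""
    return dm.guide_tree(
        n_tips, seed=int(rng.integers(2 ** 31)),
        n_subclades=max(2, n_tips // 3),
        stem=float(rng.uniform(0.05, 0.5)),
        crown=float(rng.uniform(0.02, 0.3)))


def random_matrix(rng: np.random.Generator, tree, n_chars: int,
                  p_one: float = 0.5) -> "dm.PresenceMatrix":
    data = (rng.random((tree.n_tips, n_chars)) < p_one).astype(np.uint8)
    chars = [f"c{j}" for j in range(n_chars)]
    return dm.PresenceMatrix(tree.tip_labels, chars, data)
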