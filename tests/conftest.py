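import numpy as np
import pytest

from coralphy import coalsim, treeio


@pytest.fixture(scope="session")
def coralline9_model():
    return coalsim.coralline9(stem=0.1)


@pytest.fixture(scope="session")
def groups9():
    return coalsim.coralline9_groups()


def random_binary_tree(rng, n_taxa=9, with_supports=True):
    """Random topology by sequential joins; lengths and supports randomized."""
    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = [f"{lab}:{rng.uniform(0.01, 2.0):.4f}" for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        sup = str(rng.integers(0, 101)) if with_supports else ""
        nodes.append(f"({a},{b}){sup}:{rng.uniform(0.01, 2.0):.4f}")
    return treeio.parse_newick("(" + ",".join(nodes) + ");")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
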