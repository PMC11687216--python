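import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import OtuTable, SampleMetadata


@pytest.fixture
def toy_tree():
    return TreeNode.read(["((a:1,b:1):1,c:2);"])


@pytest.fixture
def toy_table():
    counts = np.array([[5, 0], [3, 4], [0, 6]])
    return OtuTable(counts, ["a", "b", "c"], ["s1", "s2"])


@pytest.fixture
def toy_metadata():
    frame = pd.DataFrame(
        {
            "season": ["summer"] * 4,
            "layer": ["surface"] * 4,
            "fraction": ["DNA"] * 4,
            "latitude": [22.0, 22.3, 22.6, 22.9],
            "longitude": [113.5] * 4,
            "salinity": [0.2, 6.0, 19.0, 33.0],
            "NO3": [30.0, 20.0, 10.0, 5.0],
            "NH4": [9.0, 7.0, 5.0, 2.0],
        },
        index=pd.Index([f"s{i}" for i in range(1, 5)], name="sample_id"),
    )
    return SampleMetadata(frame)


def random_tree(rng, n_tips):
    """Random binary tree with exponential branch lengths (test helper)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.exponential(1.0)) + 0.05)
             for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)) + 0.05)
        parent.extend([left, right])
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    return root


def random_table(rng, n_otus, n_samples, depth=50):
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_otus)), size=n_samples).T
    # guarantee no empty sample
    counts[rng.integers(n_otus), counts.sum(axis=0) == 0] = 1
    ids = [f"t{i}" for i in range(n_otus)]
    return OtuTable(counts, ids, [f"s{j}" for j in range(n_samples)])
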