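import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from thermodiv.tables_io import OtuTable


@pytest.fixture
def three_tip_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); — total branch length 5, d(A,B)=2, d(A,C)=d(B,C)=4."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def four_tip_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("((A:1,B:2):0.5,(C:1.5,D:3):0.7);"))


@pytest.fixture
def star_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"))


@pytest.fixture
def small_table() -> OtuTable:
    """Two sites, two samples each, four OTUs."""
    counts = pd.DataFrame(
        {
            "s1": [5, 1, 0, 2],
            "s2": [3, 0, 1, 4],
            "s3": [0, 6, 2, 0],
            "s4": [1, 4, 3, 0],
        },
        index=["OTU1", "OTU2", "OTU3", "OTU4"],
    )
    site_of = {"s1": "warm", "s2": "warm", "s3": "cold", "s4": "cold"}
    return OtuTable(counts, site_of=site_of)


def random_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Independent random-join tree builder used as a fixture source."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(int(i)), nodes.pop(int(j))
        a.length = float(rng.uniform(0.05, 2.0))
        b.length = float(rng.uniform(0.05, 2.0))
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]
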