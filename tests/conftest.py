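import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizonet.types import CommunityTable


@pytest.fixture
def small_table() -> CommunityTable:
    """4 samples x 5 taxa with simple structure."""
    counts = pd.DataFrame(
        [
            [10, 10, 10, 10, 0],
            [5, 0, 5, 0, 0],
            [0, 3, 0, 7, 1],
            [2, 2, 2, 2, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["t1", "t2", "t3", "t4", "t5"],
    )
    return CommunityTable(counts)


@pytest.fixture
def cherry_tree() -> TreeNode:
    """Five-tip tree with known branch lengths."""
    return TreeNode.read(["((t1:1,t2:1):2,(t3:1,(t4:0.5,t5:0.5):0.5):2);"])


@pytest.fixture
def six_sample_groups() -> pd.Series:
    return pd.Series(
        ["a", "a", "a", "b", "b", "b"], index=[f"s{i}" for i in range(1, 7)]
    )
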