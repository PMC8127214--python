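import numpy as np
import pandas as pd
import pytest

import treeclimber as tc


@pytest.fixture
def toy_tree():
    """((A,B),C); — the smallest non-star topology: K=3, M=5, root=5."""
    return tc.parse_newick("((A,B),C);")


@pytest.fixture
def two_branch_tree():
    """Two internal branches of 4 and 6 leaves under the root."""
    return tc.parse_newick("((A,B,C,D),(E,F,G,H,I,J));")


def make_counts(tree, values, samples=None):
    """Leaf x sample DataFrame from a dict label -> list of values."""
    df = pd.DataFrame(values).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{j + 1}" for j in range(df.shape[1])]
    return df.loc[tree.leaf_labels]


def stats_from_dict(tree, p_by_node, dir_by_node, feature="abundance"):
    """NodeStats with explicit per-node p/direction (missing stays NaN)."""
    M = tree.n_nodes
    p = np.full(M + 1, np.nan)
    d = np.zeros(M + 1, dtype=np.int64)
    for i, val in p_by_node.items():
        p[i] = val
    for i, val in dir_by_node.items():
        d[i] = val
    d[np.isnan(p)] = 0
    stats = tc.NodeStats(M)
    stats.add_feature(feature, p, d)
    return stats


def clade_label_sets(tree):
    """Canonical topology signature: the leaf-label set of every node."""
    return {
        frozenset(tree.label(k) for k in tree.descendant_leaves(i))
        for i in range(1, tree.n_nodes + 1)
    }
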