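"""Node-level data generation from leaf-level or cell-level observations.

Differential abundance (DA) mode aggregates a leaf x sample count table up
the tree: the value of node ``i`` in sample ``j`` is the sum (or mean or
median) of its descendant leaves' values in that sample.  Differential state
(DS) mode aggregates per-cell feature values: the value of feature ``g`` at
node ``i`` in sample ``j`` pools all cells of sample ``j`` whose leaf lies
below ``i``.

A node x sample cell with no contributing cells (DS only) is flagged missing
(NaN) and excluded from downstream testing rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Tree, TreeError

__all__ = [
    "LeafCountTable",
    "CellTable",
    "NodeValueMatrix",
    "aggregate_da",
    "aggregate_ds",
]

_FUNS = {"sum", "mean", "median"}


@dataclass
class LeafCountTable:
    """Counts of K entities (rows) in J samples (columns), plus an optional
    two-level group factor over the samples."""

    counts: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self):
        c = self.counts
        if not isinstance(c, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("need at least 2 entities and 2 samples")
        if c.index.duplicated().any():
            raise ValueError("duplicate entity labels in counts")
        if c.columns.duplicated().any():
            raise ValueError("duplicate sample ids in counts")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("counts must be finite")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.groups is not None:
            self.groups = validate_groups(self.groups, list(c.columns))

    @property
    def n_entities(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class CellTable:
    """Per-cell feature values with cell->leaf and cell->sample assignments.

    ``cells`` must contain the columns ``leaf`` and ``sample``; every other
    column is a feature.
    """

    cells: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self):
        c = self.cells
        for col in ("leaf", "sample"):
            if col not in c.columns:
                raise ValueError(f"cell table must have a {col!r} column")
        if not self.features:
            raise ValueError("cell table must have at least one feature column")
        feat = c[self.features].to_numpy()
        if not np.issubdtype(feat.dtype, np.number) or not np.isfinite(feat).all():
            raise ValueError("feature values must be finite numbers")
        if self.groups is not None:
            self.groups = validate_groups(
                self.groups, list(pd.unique(c["sample"]))
            )

    @property
    def features(self) -> list[str]:
        return [col for col in self.cells.columns if col not in ("leaf", "sample")]


def validate_groups(groups: pd.Series, samples: list) -> pd.Series:
    """Check a sample -> group factor: covers the samples, exactly 2 levels."""
    if not isinstance(groups, pd.Series):
        raise TypeError("groups must be a pandas Series indexed by sample id")
    missing = [s for s in samples if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    groups = groups.loc[samples]
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"group factor must have exactly 2 levels, got {levels}")
    return groups


@dataclass
class NodeValueMatrix:
    """M nodes x J samples of aggregated values for one feature.

    ``values`` is indexed by node id (1..M).  ``n_cells`` (DS only) counts
    contributing cells per node x sample; zero-cell entries are NaN in
    ``values``.
    """

    values: pd.DataFrame
    fun: str
    feature: str = "abundance"
    n_cells: pd.DataFrame | None = None
    tree: Tree = field(default=None, repr=False)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def library_sizes(self) -> pd.Series:
        """Per-sample totals (the root row; requires fun='sum')."""
        if self.fun != "sum":
            raise ValueError("library sizes require sum aggregation")
        return self.values.loc[self.tree.root]


def _match_leaves(tree: Tree, labels) -> pd.Index:
    tree_set = set(tree.leaf_labels)
    data_set = set(labels)
    if tree_set != data_set:
        extra = sorted(data_set - tree_set)[:10]
        miss = sorted(tree_set - data_set)[:10]
        raise TreeError(
            "entity labels do not biject to tree leaves; "
            f"not in tree: {extra}; missing from data: {miss}"
        )
    return pd.Index(tree.leaf_labels)


def aggregate_da(tree: Tree, counts, fun: str = "sum") -> NodeValueMatrix:
    """Aggregate a leaf-level table to every tree node (DA mode).

    ``counts`` is a :class:`LeafCountTable` or a bare DataFrame whose row
    labels biject to the tree's leaf labels.  With ``fun='sum'`` the root row
    equals the per-sample library sizes and every internal node's row equals
    the sum of its children's rows.
    """
    if isinstance(counts, LeafCountTable):
        df = counts.counts
    else:
        df = counts
    if fun not in _FUNS:
        raise ValueError(f"fun must be one of {sorted(_FUNS)}")
    order = _match_leaves(tree, df.index)
    leaf = df.loc[order].to_numpy(dtype=float)  # K x J in leaf-id order
    K, J = leaf.shape
    M = tree.n_nodes
    out = np.empty((M + 1, J), dtype=float)
    out[1 : K + 1] = leaf
    if fun == "sum":
        for i in tree.postorder():
            if not tree.is_leaf(i):
                out[i] = sum(out[c] for c in tree.children(i))
    else:
        agg = np.mean if fun == "mean" else np.median
        for i in tree.internal_nodes:
            rows = sorted(tree.descendant_leaves(i))
            out[i] = agg(leaf[np.asarray(rows) - 1], axis=0)
    values = pd.DataFrame(out[1:], index=pd.RangeIndex(1, M + 1), columns=df.columns)
    values.index.name = "node_id"
    return NodeValueMatrix(values=values, fun=fun, tree=tree)


def aggregate_ds(tree: Tree, cells: CellTable, fun: str = "median") -> dict[str, NodeValueMatrix]:
    """Aggregate cell-level feature values to every node (DS mode).

    Returns one :class:`NodeValueMatrix` per feature; node x sample entries
    with no contributing cells are NaN with ``n_cells`` 0.
    """
    if fun not in _FUNS:
        raise ValueError(f"fun must be one of {sorted(_FUNS)}")
    df = cells.cells.reset_index(drop=True)
    unknown = sorted(set(df["leaf"]) - set(tree.leaf_labels))
    if unknown:
        raise TreeError(f"cells mapped to unknown leaves: {unknown[:10]}")
    samples = list(pd.unique(df["sample"]))
    leaf_id = {lab: tree.node_by_label(lab) for lab in set(df["leaf"])}
    M = tree.n_nodes
    agg = {"sum": np.sum, "mean": np.mean, "median": np.median}[fun]

    # cell values bucketed by (leaf id, sample)
    buckets: dict[tuple[int, object], np.ndarray] = {}
    for (leaf, sample), sub in df.groupby(["leaf", "sample"], sort=False):
        buckets[(leaf_id[leaf], sample)] = sub.index.to_numpy()

    result: dict[str, NodeValueMatrix] = {}
    for g in cells.features:
        col = df[g].to_numpy(dtype=float)
        vals = np.full((M + 1, len(samples)), np.nan)
        ncell = np.zeros((M + 1, len(samples)), dtype=np.int64)
        for i in range(1, M + 1):
            below = tree.descendant_leaves(i)
            for j, sample in enumerate(samples):
                idx = [buckets[(l, sample)] for l in below if (l, sample) in buckets]
                if idx:
                    pool = col[np.concatenate(idx)]
                    vals[i, j] = agg(pool)
                    ncell[i, j] = pool.size
        values = pd.DataFrame(vals[1:], index=pd.RangeIndex(1, M + 1), columns=samples)
        values.index.name = "node_id"
        counts = pd.DataFrame(ncell[1:], index=pd.RangeIndex(1, M + 1), columns=samples)
        result[g] = NodeValueMatrix(
            values=values, fun=fun, feature=g, n_cells=counts, tree=tree
        )
    return result
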