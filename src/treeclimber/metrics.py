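"""Leaf-level confusion metrics and the repetition-level benchmark loop.

Rejections of internal nodes are expanded to their descendant leaves
before scoring, so TPR and FDR are always computed on the leaf set.  An
empty call set has FDR 0 by convention (a method rejecting nothing has
both TPR and FDR equal to zero).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .candidate import propose_candidates
from .evaluation import bh_adjust, climb
from .node_tests import nb_glm_node_test, wilcoxon_node_test
from .aggregation import aggregate_da
from .simulate import (
    DMParams,
    apply_bs,
    apply_ss,
    apply_us,
    pick_signal_branches,
    simulate_dataset,
    synthetic_params,
    synthetic_tree,
)
from .tree import Tree

__all__ = [
    "ConfusionSummary",
    "leaf_confusion",
    "benchmark",
    "summarize_benchmark",
    "null_internal_representation_rate",
]


def null_internal_representation_rate(
    n_branches: int,
    rng: np.random.Generator,
    n_leaves: int = 3,
    t: float = 1.0,
) -> float:
    """Monte-Carlo probability that the climbing stop rule represents a
    signal-free star branch by its internal node.

    Each simulated branch carries independent Uniform(0, 1) p-values on all
    nodes, equiprobable +/-1 directions on the leaves, and the sign of the
    leaf aggregate as the internal node's direction.  At ``t = 1`` the
    indicator in the U score always fires, so the internal node is selected
    exactly when all leaf directions agree (2^(1-n_leaves) for a star) and
    its own p-value clears the 0.05 admission threshold — about 0.0125 for
    three leaves.
    """
    from .candidate import propose_candidate
    from .node_tests import NodeStats
    from .tree import parse_newick

    if n_branches < 1:
        raise ValueError("need at least one simulated branch")
    tree = parse_newick("(" + ",".join(f"L{i}" for i in range(n_leaves)) + ");")
    M = tree.n_nodes
    internal = tree.root
    p_all = rng.uniform(size=(n_branches, M + 1))
    signs = rng.choice([-1, 1], size=(n_branches, n_leaves))
    tie_break = rng.choice([-1, 1], size=n_branches)
    hits = 0
    for b in range(n_branches):
        d = np.zeros(M + 1, dtype=np.int64)
        d[1 : n_leaves + 1] = signs[b]
        agg = signs[b].sum()
        d[internal] = np.sign(agg) if agg != 0 else tie_break[b]
        stats = NodeStats(M)
        stats.add_feature("abundance", p_all[b], d)
        cand = propose_candidate(tree, stats, t)
        if cand.termini == (internal,):
            hits += 1
    return hits / n_branches


@dataclass
class ConfusionSummary:
    """Leaf-level confusion counts with derived TPR and FDR."""

    tp: int
    fp: int
    fn: int
    tpr: float
    fdr: float
    method: str = ""
    alpha: float = np.nan
    rep: int = -1


def leaf_confusion(
    result,
    truth: Iterable[str],
    tree: Tree,
    method: str = "",
    alpha: float = np.nan,
    rep: int = -1,
) -> ConfusionSummary:
    """Score a call set against the true leaf set.

    ``result`` is either a SelectionResult (its rejected nodes are expanded
    to descendant leaves) or an iterable of called leaf labels.  ``truth``
    is the set of truly differential leaf labels.
    """
    leaf_set = set(tree.leaf_labels)
    truth = set(truth)
    unknown = truth - leaf_set
    if unknown:
        raise ValueError(f"truth contains unknown leaf labels: {sorted(unknown)[:10]}")
    if hasattr(result, "rejected_leaf_labels"):
        called = set(result.rejected_leaf_labels)
    else:
        called = set(result)
        unknown = called - leaf_set
        if unknown:
            raise ValueError(
                f"called set contains unknown leaf labels: {sorted(unknown)[:10]}"
            )
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tpr=tpr, fdr=fdr,
                            method=method, alpha=alpha, rep=rep)


def _bh_leaf_calls(stats, tree: Tree, alpha: float) -> set[str]:
    """Leaf-level BH comparator: adjust the leaf p-values only."""
    p, _ = stats.get()
    leaf_p = p[1 : tree.n_leaves + 1]
    ok = ~np.isnan(leaf_p)
    called: set[str] = set()
    if ok.any():
        adj = bh_adjust(leaf_p[ok])
        ids = np.arange(1, tree.n_leaves + 1)[ok][adj <= alpha]
        called = {tree.label(int(i)) for i in ids}
    return called


_SCENARIOS = {"BS": apply_bs, "US": apply_us, "SS": apply_ss}


def benchmark(
    scenario: str = "BS",
    n_reps: int = 50,
    n_per_group: int = 10,
    alphas: Sequence[float] = (0.05,),
    K: int = 100,
    theta: float = 0.02,
    depth_range: tuple[int, int] = (10_000, 50_000),
    branch_leaves: tuple[int, int] = (5, 10),
    ss_fraction: float = 0.5,
    engine: str = "nb",
    methods: Sequence[str] = ("treeclimbR", "BH"),
    seed: int = 0,
    tree: Tree | None = None,
    params: DMParams | None = None,
) -> pd.DataFrame:
    """Repetition-level benchmark of tree-aware selection against leaf-level
    BH on simulated Dirichlet-multinomial data.

    A random binary tree and control parameters are drawn once; the two
    signal branches are fixed across repetitions (each repetition redraws
    counts only).  Per-repetition seeds derive deterministically from
    ``seed``, so the output table is bit-reproducible.  Returns a
    long-format table with one row per (repetition, method, alpha).
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be one of {sorted(_SCENARIOS)}")
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    root_seq = np.random.SeedSequence(seed)
    setup_rng = np.random.default_rng(root_seq.spawn(1)[0])
    if tree is None:
        tree = synthetic_tree(K, setup_rng)
    if params is None:
        params = synthetic_params(
            tree.n_leaves, theta=theta, depth_range=depth_range, rng=setup_rng,
            labels=tuple(tree.leaf_labels),
        )
    A, B = pick_signal_branches(
        tree, params, setup_rng,
        min_leaves=branch_leaves[0], max_leaves=branch_leaves[1],
    )
    if scenario == "BS":
        _, spec = apply_bs(params, A, B, tree)
    elif scenario == "US":
        _, spec = apply_us(params, A, B, tree, setup_rng)
    else:
        _, spec = apply_ss(params, A, B, tree, setup_rng, fraction=ss_fraction)

    rows = []
    rep_seqs = root_seq.spawn(n_reps + 1)[1:]
    for rep, seq in enumerate(rep_seqs):
        rng = np.random.default_rng(seq)
        table, truth = simulate_dataset(
            tree, params, spec, n_per_group, n_per_group, rng
        )
        values = aggregate_da(tree, table, fun="sum")
        if engine == "nb":
            stats = nb_glm_node_test(values, table.groups)
        elif engine == "wilcoxon":
            stats = wilcoxon_node_test(values, table.groups, normalize=True)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        candidates = propose_candidates(tree, stats)
        for alpha in alphas:
            for method in methods:
                if method == "treeclimbR":
                    sel = climb(tree, stats, alpha=alpha, candidates=candidates)
                    summary = leaf_confusion(
                        sel, truth, tree, method=method, alpha=alpha, rep=rep
                    )
                elif method == "BH":
                    called = _bh_leaf_calls(stats, tree, alpha)
                    summary = leaf_confusion(
                        called, truth, tree, method=method, alpha=alpha, rep=rep
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append(asdict(summary))
    columns = ["rep", "method", "alpha", "tp", "fp", "fn", "tpr", "fdr"]
    return pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Per (method, alpha) means of TPR and FDR with Monte-Carlo standard
    errors over repetitions."""
    if table.empty:
        return pd.DataFrame(
            columns=["method", "alpha", "n_reps", "tpr_mean", "tpr_se", "fdr_mean", "fdr_se"]
        )

    def agg(sub: pd.DataFrame) -> pd.Series:
        n = len(sub)
        return pd.Series(
            {
                "n_reps": n,
                "tpr_mean": sub["tpr"].mean(),
                "tpr_se": sub["tpr"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "fdr_mean": sub["fdr"].mean(),
                "fdr_se": sub["fdr"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            }
        )

    out = (
        table.groupby(["method", "alpha"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n_reps"] = out["n_reps"].astype(int)
    return out
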