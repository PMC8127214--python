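"""Candidate evaluation and data-driven selection.

Each candidate's hypothesis list (its terminus nodes; node x feature pairs
for pooled candidates) is corrected with Benjamini-Hochberg.  Rejecting an
internal node rejects all of its descendant leaves.  From the rejected
nodes, the mean signal-branch size is estimated as r_hat = l / s (l =
descendant leaves of rejected nodes, s = rejected nodes; r_hat = 1 when
nothing is rejected), and a candidate generated at t is admissible only if

    t <= 2 * alpha * (r_hat - 1)

which keeps the leaf-level FDR at the nominal alpha.  Among admissible
candidates the winner maximizes the number of rejected leaves, breaking
ties by fewest rejected nodes, then by smallest t (closest to the leaf
level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import CellTable, LeafCountTable, aggregate_da, aggregate_ds
from .candidate import (
    DEFAULT_NODE_P_THRESHOLD,
    Candidate,
    default_t_grid,
    propose_candidates,
)
from .node_tests import NodeStats, nb_glm_node_test, wilcoxon_node_test
from .tree import Tree

__all__ = [
    "CandidateEvaluation",
    "SelectionResult",
    "bh_adjust",
    "evaluate_candidate",
    "t_upper",
    "select_candidate",
    "climb",
    "treeclimb_run",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    Rejection at level alpha is equivalent to adjusted <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no missing entries")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def t_upper(alpha: float, r: float) -> float:
    """Upper bound of the admissible tuning range, 2*alpha*(r-1), clipped
    to 1.  At r = 1 the bound is 0: signals do not cluster on the tree and
    the leaf level must be used."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if r < 1.0:
        raise ValueError(f"mean signal-branch size r must be >= 1, got {r}")
    return float(min(1.0, 2.0 * alpha * (r - 1.0)))


@dataclass
class CandidateEvaluation:
    """Rejection summary of one candidate after BH correction.

    m counts tested hypotheses (node x feature pairs with a p-value), R the
    rejected hypotheses, s the distinct rejected nodes, l (= R_L) the
    distinct descendant leaves of rejected nodes, r_hat = l/s the mean
    signal-branch size (1 when s = 0).
    """

    candidate: Candidate
    alpha: float
    m: int
    R: int
    R_L: int
    s: int
    l: int
    r_hat: float
    t_max: float
    admissible: bool
    rejected: dict[str, tuple[int, ...]] = field(default_factory=dict)


def evaluate_candidate(
    candidate: Candidate,
    stats: NodeStats,
    tree: Tree,
    alpha: float = 0.05,
) -> CandidateEvaluation:
    """BH-correct one candidate and derive (m, R, R_L, s, l, r_hat) and the
    admissibility of its tuning value.

    Candidate nodes with a missing p-value (possible only for leaves whose
    data carry no information, e.g. all-zero counts) are excluded from the
    hypothesis list and can never be rejected.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    feats, nodes, ps = [], [], []
    for g, termini in candidate.per_feature().items():
        p = stats.p[g]
        for i in termini:
            if np.isnan(p[i]):
                continue
            feats.append(g)
            nodes.append(i)
            ps.append(p[i])
    m = len(ps)
    rejected: dict[str, list[int]] = {}
    if m:
        adj = bh_adjust(np.asarray(ps))
        for g, i, a in zip(feats, nodes, adj):
            if a <= alpha:
                rejected.setdefault(g, []).append(i)
    R = sum(len(v) for v in rejected.values())
    rej_nodes = set().union(*rejected.values()) if rejected else set()
    s = len(rej_nodes)
    leaves: set[int] = set()
    for i in rej_nodes:
        leaves |= tree.descendant_leaves(i)
    l = len(leaves)
    r_hat = max(1.0, l / s) if s > 0 else 1.0
    t_max = t_upper(alpha, r_hat)
    admissible = candidate.t == 0.0 or candidate.t <= t_max + 1e-12
    return CandidateEvaluation(
        candidate=candidate,
        alpha=alpha,
        m=m,
        R=R,
        R_L=l,
        s=s,
        l=l,
        r_hat=r_hat,
        t_max=t_max,
        admissible=admissible,
        rejected={g: tuple(sorted(v)) for g, v in rejected.items()},
    )


@dataclass
class SelectionResult:
    """Winning candidate with its rejections and the full evaluation table."""

    candidate: Candidate
    alpha: float
    rejected: dict[str, tuple[int, ...]]
    rejected_leaves: frozenset[int]
    rejected_leaf_labels: frozenset[str]
    evaluations: list[CandidateEvaluation] = field(repr=False)

    @property
    def t(self) -> float:
        return self.candidate.t

    def table(self) -> pd.DataFrame:
        """Per-candidate summary mirroring the (t, m, R, R_L, ...) layout."""
        rows = [
            {
                "t": e.candidate.t,
                "feature": e.candidate.feature,
                "m": e.m,
                "R": e.R,
                "R_L": e.R_L,
                "s": e.s,
                "l": e.l,
                "r_hat": e.r_hat,
                "t_max": e.t_max,
                "admissible": e.admissible,
                "selected": e.candidate.t == self.candidate.t
                and e.candidate.termini == self.candidate.termini,
            }
            for e in self.evaluations
        ]
        return pd.DataFrame(rows).sort_values("t", ignore_index=True)

    def results_frame(self, stats: NodeStats, tree: Tree) -> pd.DataFrame:
        """Rejected nodes of the winning candidate, one row per
        (feature, node), with p, direction and descendant-leaf count."""
        rows = []
        for g, termini in self.candidate.per_feature().items():
            ps = [stats.p[g][i] for i in termini if not np.isnan(stats.p[g][i])]
            order = [i for i in termini if not np.isnan(stats.p[g][i])]
            adj = dict(zip(order, bh_adjust(ps))) if order else {}
            for i in self.rejected.get(g, ()):
                rows.append(
                    {
                        "feature": g,
                        "node_id": i,
                        "label": tree.label(i),
                        "p": stats.p[g][i],
                        "adjusted_p": adj[i],
                        "direction": int(stats.direction[g][i]),
                        "n_descendant_leaves": tree.n_descendant_leaves(i),
                        "selected_t": self.candidate.t,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "feature",
                "node_id",
                "label",
                "p",
                "adjusted_p",
                "direction",
                "n_descendant_leaves",
                "selected_t",
            ],
        )


def select_candidate(
    evaluations: list[CandidateEvaluation],
    tree: Tree,
) -> SelectionResult:
    """Pick the best candidate: (i) drop inadmissible ones, (ii) maximize
    rejected leaves R_L, (iii) minimize rejected nodes s; remaining ties go
    to the smallest t.  The t = 0 (leaf-level) candidate is always
    admissible, so a winner always exists."""
    if not evaluations:
        raise ValueError("no evaluations to select from")
    alphas = {e.alpha for e in evaluations}
    if len(alphas) != 1:
        raise ValueError("evaluations must share one alpha")
    admissible = [e for e in evaluations if e.admissible]
    if not admissible:
        raise ValueError("no admissible candidate (the t=0 evaluation is required)")
    best = min(admissible, key=lambda e: (-e.R_L, e.s, e.candidate.t))
    leaves: set[int] = set()
    for nodes in best.rejected.values():
        for i in nodes:
            leaves |= tree.descendant_leaves(i)
    return SelectionResult(
        candidate=best.candidate,
        alpha=best.alpha,
        rejected=dict(best.rejected),
        rejected_leaves=frozenset(leaves),
        rejected_leaf_labels=frozenset(tree.label(i) for i in leaves),
        evaluations=list(evaluations),
    )


def climb(
    tree: Tree,
    stats: NodeStats,
    alpha: float = 0.05,
    t_grid=None,
    node_p_threshold: float = DEFAULT_NODE_P_THRESHOLD,
    candidates: list[Candidate] | None = None,
) -> SelectionResult:
    """Propose candidates over the t grid, evaluate each at ``alpha`` and
    select the winner.  Precomputed ``candidates`` (which do not depend on
    alpha) may be passed to amortize repeated selection at several alphas."""
    if candidates is None:
        candidates = propose_candidates(tree, stats, t_grid, node_p_threshold)
    evaluations = [evaluate_candidate(c, stats, tree, alpha) for c in candidates]
    return select_candidate(evaluations, tree)


def treeclimb_run(
    tree: Tree,
    counts=None,
    cells: CellTable | None = None,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
    engine: str | None = None,
    fun: str | None = None,
    t_grid=None,
    node_p_threshold: float = DEFAULT_NODE_P_THRESHOLD,
    reference=None,
) -> tuple[SelectionResult, NodeStats]:
    """End-to-end pipeline: aggregate, test every node, propose candidates
    over the t grid, evaluate and select.

    DA mode (``counts`` given): default sum aggregation with the
    negative-binomial engine (``engine='nb'``); ``engine='wilcoxon'`` tests
    library-size-normalized values instead.  DS mode (``cells`` given):
    default median aggregation with the Wilcoxon engine per feature, pooling
    per-feature candidates into global ones.

    Returns the :class:`SelectionResult` together with the node-level
    statistics that produced it.
    """
    if (counts is None) == (cells is None):
        raise ValueError("provide exactly one of counts (DA) or cells (DS)")
    if counts is not None:
        if isinstance(counts, LeafCountTable):
            if groups is None:
                groups = counts.groups
        if groups is None:
            raise ValueError("groups are required")
        engine = engine or "nb"
        fun = fun or "sum"
        values = aggregate_da(tree, counts, fun=fun)
        if engine == "nb":
            stats = nb_glm_node_test(values, groups, reference=reference)
        elif engine == "wilcoxon":
            stats = wilcoxon_node_test(
                values, groups, normalize=(fun == "sum"), reference=reference
            )
        else:
            raise ValueError(f"unknown DA engine {engine!r}")
    else:
        if groups is None:
            groups = cells.groups
        if groups is None:
            raise ValueError("groups are required")
        engine = engine or "wilcoxon"
        if engine != "wilcoxon":
            raise ValueError("DS mode supports the wilcoxon engine only")
        fun = fun or "median"
        per_feature = aggregate_ds(tree, cells, fun=fun)
        stats = None
        for g, values in per_feature.items():
            s = wilcoxon_node_test(values, groups, reference=reference)
            stats = s if stats is None else stats.merged(s)
    result = climb(tree, stats, alpha=alpha, t_grid=t_grid, node_p_threshold=node_p_threshold)
    return result, stats
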