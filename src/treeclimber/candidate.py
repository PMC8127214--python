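"""Candidate proposal: U scores and the root-to-leaf climbing rule.

For a tuning value ``t`` in [0, 1], every node ``k`` gets a signed
significance indicator

    q_k(t) = sign_k * I(p_k <= t)          (0 when p_k is missing)

and every node ``i`` a coherence score

    U_i(t) = | sum_{k in B(i)} q_k(t) | / |B(i)|

where B(i) is the node plus all its descendants.  U_i(t) = 1 exactly when
every node in the branch is significant at ``t`` with one shared non-zero
direction.

A candidate at ``t`` is proposed by climbing from the root toward the
leaves: each path stops at the first node with U_i(t) = 1 and p_i < 0.05
(the internal-node admission threshold), or at the leaf.  The termini are
non-nested and their descendant-leaf sets partition the leaves.  With
several features (DS mode), each feature climbs the tree independently and
the per-feature candidates at a common ``t`` are pooled into a global
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .node_tests import NodeStats
from .tree import Tree

__all__ = [
    "Candidate",
    "q_score",
    "u_score",
    "propose_candidate",
    "propose_candidates",
    "default_t_grid",
    "pool_candidates",
    "DEFAULT_NODE_P_THRESHOLD",
]

#: Admission threshold for internal termini (the p_i < 0.05 part of the
#: stop rule).  Under the null this keeps the chance of representing a
#: three-leaf branch by its internal node at about 1/4 * 0.05.
DEFAULT_NODE_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class Candidate:
    """A set of non-nested terminus nodes proposed at tuning value ``t``.

    ``provenance`` maps each feature to its own terminus tuple for pooled
    (multi-feature) candidates; the pooled node set may contain nested nodes
    across features, the per-feature lists never do.
    """

    t: float
    termini: tuple[int, ...]
    feature: str = "abundance"
    provenance: Mapping[str, tuple[int, ...]] | None = None

    def per_feature(self) -> dict[str, tuple[int, ...]]:
        if self.provenance is not None:
            return dict(self.provenance)
        return {self.feature: self.termini}


def _check_t(t: float) -> float:
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"tuning value t must be in [0, 1], got {t}")
    return t


def q_score(p: float | None, direction: int, t: float) -> int:
    """Signed significance indicator of a single node."""
    t = _check_t(t)
    if p is None or np.isnan(p):
        return 0
    return int(direction) if p <= t else 0


def _branch_sums(
    tree: Tree,
    p: np.ndarray,
    direction: np.ndarray,
    t: float,
    count_missing: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer sum of q over B(i) and |B(i)| for every node (vectorized
    post-order accumulation).  With ``count_missing=False`` nodes with
    missing p are dropped from the branch size n_B."""
    missing = np.isnan(p)
    q = np.where(missing, 0, direction * (np.where(missing, 2.0, p) <= t)).astype(np.int64)
    S = np.zeros(tree.n_nodes + 1, dtype=np.int64)
    nB = np.zeros(tree.n_nodes + 1, dtype=np.int64)
    own = np.where(missing & (not count_missing), 0, 1).astype(np.int64)
    for i in tree.postorder():
        S[i] = q[i] + sum(S[c] for c in tree.children(i))
        nB[i] = own[i] + sum(nB[c] for c in tree.children(i))
    return S, nB


def u_score(
    tree: Tree,
    stats: NodeStats,
    i: int,
    t: float,
    feature: str | None = None,
    count_missing: bool = True,
) -> float:
    """U_i(t): absolute mean signed indicator over the branch set B(i)."""
    t = _check_t(t)
    p, d = stats.get(feature)
    tree._check(i)
    total = 0
    n = 0
    for k in tree.branch_set(i):
        if np.isnan(p[k]):
            if count_missing:
                n += 1
            continue
        total += q_score(p[k], d[k], t)
        n += 1
    return abs(total) / n if n else 0.0


def propose_candidate(
    tree: Tree,
    stats: NodeStats,
    t: float,
    feature: str | None = None,
    node_p_threshold: float = DEFAULT_NODE_P_THRESHOLD,
    count_missing: bool = True,
) -> Candidate:
    """Climb from the root and return the candidate at tuning value ``t``.

    A node is a terminus iff it is the first node on its root-to-leaf path
    with U_i(t) = 1 and p_i < ``node_p_threshold``, or a leaf.  Nodes with
    missing p are never termini (climbing continues past them), so the
    termini always partition the leaf set.
    """
    t = _check_t(t)
    if feature is None and len(stats.features) == 1:
        feature = stats.features[0]
    p, d = stats.get(feature)
    S, nB = _branch_sums(tree, p, d, t, count_missing)
    # U == 1 checked in exact integer arithmetic: |S| == n_B > 0
    coherent = (np.abs(S) == nB) & (nB > 0)
    admissible_p = ~np.isnan(p) & (np.where(np.isnan(p), 1.0, p) < node_p_threshold)
    stop = coherent & admissible_p
    termini: list[int] = []
    stack = [tree.root]
    while stack:
        i = stack.pop()
        if stop[i] or tree.is_leaf(i):
            termini.append(i)
        else:
            stack.extend(tree.children(i))
    return Candidate(t=t, termini=tuple(sorted(termini)), feature=feature)


def default_t_grid(stats: NodeStats | None = None) -> np.ndarray:
    """The fixed 25-point exploration grid over [0, 1]:
    {0, 0.01, 0.02, 0.03, 0.04} followed by 0.05 steps up to 1."""
    grid = np.concatenate([np.arange(0.0, 0.05, 0.01), np.arange(0.05, 1.0001, 0.05)])
    return np.round(grid, 10)


def pool_candidates(per_feature: Mapping[str, Candidate]) -> Candidate:
    """Union the per-feature candidates at a common ``t`` into a global one."""
    if not per_feature:
        raise ValueError("no candidates to pool")
    ts = {c.t for c in per_feature.values()}
    if len(ts) != 1:
        raise ValueError(f"candidates must share one t, got {sorted(ts)}")
    termini = sorted(set().union(*(c.termini for c in per_feature.values())))
    provenance = {g: tuple(c.termini) for g, c in per_feature.items()}
    return Candidate(
        t=next(iter(ts)),
        termini=tuple(termini),
        feature="global",
        provenance=provenance,
    )


def propose_candidates(
    tree: Tree,
    stats: NodeStats,
    t_grid=None,
    node_p_threshold: float = DEFAULT_NODE_P_THRESHOLD,
    count_missing: bool = True,
) -> list[Candidate]:
    """One candidate per grid value; multi-feature stats are pooled per t."""
    if t_grid is None:
        t_grid = default_t_grid(stats)
    out = []
    for t in t_grid:
        per_feature = {
            g: propose_candidate(tree, stats, t, g, node_p_threshold, count_missing)
            for g in stats.features
        }
        if len(per_feature) == 1:
            out.append(next(iter(per_feature.values())))
        else:
            out.append(pool_candidates(per_feature))
    return out
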