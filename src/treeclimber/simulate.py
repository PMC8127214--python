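"""Dirichlet-multinomial count simulation with tree-located signals.

Counts of K taxa in a sample of depth n are drawn from a
Dirichlet-multinomial DM(n, alpha) with alpha_k = pi_k * (1 - theta) / theta,
where pi is the expected proportion vector and theta in (0, 1) the
overdispersion (theta -> 0 recovers the multinomial).  Group differences
are introduced by modifying pi, never the realized counts, so the relative
abundance of unaffected taxa is identical between groups.

Three scenarios place signal on two randomly chosen, non-nested branches A
and B of the tree:

* BS (balanced): proportions are swapped between A and B with one shared
  fold change r = sum(pi_B) / sum(pi_A) — pi doubles on A and halves on B
  when r = 2;
* US (unbalanced): as BS, but each leaf of a signal branch gets its own
  positive multiplier (same direction within a branch, heterogeneous
  magnitude) with branch masses still swapped exactly;
* SS (sporadic): the BS swap restricted to random subsets of the two
  branches' leaves; the remaining leaves keep pi exactly.

Every operation takes an explicit numpy Generator and is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .aggregation import LeafCountTable
from .tree import Tree, _Node

__all__ = [
    "DMParams",
    "ScenarioSpec",
    "estimate_dm",
    "sample_dm",
    "pick_signal_branches",
    "apply_bs",
    "apply_us",
    "apply_ss",
    "simulate_dataset",
    "synthetic_tree",
    "synthetic_params",
]

_THETA_MIN = 1e-6
_THETA_MAX = 1.0 - 1e-6


@dataclass
class DMParams:
    """Dirichlet-multinomial parameters over K leaves.

    ``pi`` sums to 1; ``theta`` in [0, 1) is the overdispersion;
    ``depths`` is the pool of per-sample totals resampled (with
    replacement) at simulation time; ``labels`` aligns pi with tree leaf
    labels (leaf-id order).
    """

    pi: np.ndarray
    theta: float
    depths: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.pi.ndim != 1 or self.pi.size < 2:
            raise ValueError("pi must be a vector over at least 2 leaves")
        if (self.pi < 0).any() or not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must be nonnegative and sum to 1")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if self.depths.size == 0 or (self.depths < 0).any():
            raise ValueError("depth pool must be nonempty and nonnegative")
        if self.labels is not None and len(self.labels) != self.pi.size:
            raise ValueError("labels must match pi")

    @property
    def alpha(self) -> np.ndarray:
        """alpha_k = pi_k * (1 - theta) / theta (requires theta > 0)."""
        if self.theta <= 0.0:
            raise ValueError("alpha is undefined at theta = 0 (multinomial limit)")
        return self.pi * (1.0 - self.theta) / self.theta


@dataclass
class ScenarioSpec:
    """Bookkeeping of one simulated signal scenario.

    ``truth`` maps affected leaf labels to the direction of change in the
    treatment group (+1 up, -1 down); leaves outside ``truth`` have
    identical pi in both groups.  ``treatment`` holds the modified
    parameters used for treatment samples.
    """

    scenario: str
    branch_a: int
    branch_b: int
    fold_change: float
    treatment: DMParams
    truth: dict[str, int]
    affected_a: tuple[int, ...] = ()
    affected_b: tuple[int, ...] = ()
    multipliers: dict[int, float] | None = None


# ------------------------------------------------------------------ fitting


def _dm_negloglik(log_alpha: np.ndarray, x: np.ndarray, n: np.ndarray):
    a = np.exp(log_alpha)
    A = a.sum()
    ll = (
        x.shape[0] * 0.0
        + np.sum(gammaln(A) - gammaln(n + A))
        + np.sum(gammaln(x + a) - gammaln(a))
    )
    # gradient wrt log alpha
    g = a * (
        np.sum(digamma(x + a) - digamma(a), axis=0)
        + x.shape[0] * digamma(A)
        - np.sum(digamma(n + A))
    )
    return -ll, -g


def estimate_dm(counts) -> DMParams:
    """Maximum-likelihood (pi, theta) from a leaf x sample count table.

    The likelihood is maximized over log alpha (moment-estimator start,
    quasi-Newton iterations, convergence when successive log-likelihoods
    move by < 1e-8); theta_hat = 1 / (1 + sum alpha) is clamped to
    [1e-6, 1 - 1e-6].  The observed column totals become the depth pool.
    """
    if isinstance(counts, LeafCountTable):
        df = counts.counts
    else:
        df = pd.DataFrame(counts)
    x = df.to_numpy(dtype=float).T  # samples x K
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 leaves")
    n = x.sum(axis=1)
    if (n == 0).any():
        raise ValueError("every sample must have a nonzero total count")

    # moment initialization
    props = x / n[:, None]
    pi0 = np.clip(props.mean(axis=0), 1e-10, None)
    pi0 = pi0 / pi0.sum()
    v = props.var(axis=0, ddof=1)
    denom = pi0 * (1.0 - pi0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = v / denom
    theta0 = float(np.clip(np.nanmedian(ratios[denom > 1e-12]), 1e-4, 0.5))
    a0 = pi0 * (1.0 - theta0) / theta0

    res = minimize(
        _dm_negloglik,
        np.log(a0),
        args=(x, n),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(1e-8), np.log(1e8))] * x.shape[1],
        options={"maxiter": 1000, "ftol": 1e-8 / max(1.0, abs(_dm_negloglik(np.log(a0), x, n)[0]))},
    )
    a = np.exp(res.x)
    A = a.sum()
    pi = a / A
    theta = float(np.clip(1.0 / (1.0 + A), _THETA_MIN, _THETA_MAX))
    return DMParams(
        pi=pi,
        theta=theta,
        depths=n.astype(np.int64),
        labels=tuple(str(i) for i in df.index),
    )


# ----------------------------------------------------------------- sampling


def sample_dm(n: int, params: DMParams, rng: np.random.Generator) -> np.ndarray:
    """One count vector: p ~ Dirichlet(alpha), counts ~ Multinomial(n, p).

    At theta = 0 the draw is plain multinomial with probabilities pi.
    """
    if n < 0:
        raise ValueError(f"total count must be >= 0, got {n}")
    K = params.pi.size
    if n == 0:
        return np.zeros(K, dtype=np.int64)
    if params.theta <= 0.0:
        return rng.multinomial(n, params.pi)
    # gamma-normalized Dirichlet; robust to zero-mass components
    g = rng.gamma(np.clip(params.alpha, 1e-300, None), 1.0)
    g[params.pi == 0] = 0.0
    total = g.sum()
    p = g / total if total > 0 else params.pi
    return rng.multinomial(n, p)


def synthetic_params(
    K: int,
    theta: float = 0.02,
    depth_range: tuple[int, int] = (10_000, 50_000),
    pool_size: int = 150,
    concentration: float = 1.0,
    rng: np.random.Generator | None = None,
    labels: tuple[str, ...] | None = None,
) -> DMParams:
    """Fully synthetic control-group parameters: pi from a symmetric
    Dirichlet(concentration) draw and a uniform integer depth pool."""
    rng = np.random.default_rng() if rng is None else rng
    pi = rng.dirichlet(np.full(K, concentration))
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=pool_size)
    return DMParams(pi=pi, theta=theta, depths=depths, labels=labels)


# ----------------------------------------------------------------- scenarios


def pick_signal_branches(
    tree: Tree,
    params: DMParams,
    rng: np.random.Generator,
    min_leaves: int = 2,
    max_leaves: int | None = None,
    min_prop: float = 0.0,
) -> tuple[int, int]:
    """Sample two non-nested internal nodes uniformly among all feasible
    pairs (leaf count within [min_leaves, max_leaves], branch mass >=
    min_prop)."""
    max_leaves = tree.n_leaves if max_leaves is None else max_leaves
    if min_leaves > tree.n_leaves:
        raise ValueError(
            f"min_leaves={min_leaves} exceeds the tree's {tree.n_leaves} leaves"
        )
    feasible = []
    for i in tree.internal_nodes:
        b = tree.descendant_leaves(i)
        if not (min_leaves <= len(b) <= max_leaves):
            continue
        mass = params.pi[np.asarray(sorted(b)) - 1].sum()
        if mass < min_prop or mass <= 0:
            continue
        feasible.append((i, b))
    pairs = [
        (i, j)
        for ai, (i, bi) in enumerate(feasible)
        for (j, bj) in feasible[ai + 1 :]
        if not (bi & bj)
    ]
    if not pairs:
        raise ValueError(
            "no feasible non-nested branch pair under constraints "
            f"(min_leaves={min_leaves}, max_leaves={max_leaves}, min_prop={min_prop})"
        )
    a, b = pairs[int(rng.integers(len(pairs)))]
    return (a, b) if rng.integers(2) == 0 else (b, a)


def _leaf_indices(tree: Tree, node: int) -> np.ndarray:
    return np.asarray(sorted(tree.descendant_leaves(node)), dtype=np.int64) - 1


def _truth(tree: Tree, idx_a, idx_b, r: float) -> dict[str, int]:
    if r == 1.0:
        return {}
    up = 1 if r > 1.0 else -1
    labels = tree.leaf_labels
    truth = {labels[k]: up for k in idx_a}
    truth.update({labels[k]: -up for k in idx_b})
    return truth


def apply_bs(
    params: DMParams, A: int, B: int, tree: Tree
) -> tuple[DMParams, ScenarioSpec]:
    """Balanced signal: swap the proportion masses of branches A and B.

    Every leaf of A is multiplied by r = sum(pi_B) / sum(pi_A) and every
    leaf of B divided by it; all other leaves keep pi exactly, and the
    treatment pi still sums to 1.
    """
    ia, ib = _leaf_indices(tree, A), _leaf_indices(tree, B)
    if set(ia) & set(ib):
        raise ValueError("signal branches A and B must be disjoint")
    mass_a, mass_b = params.pi[ia].sum(), params.pi[ib].sum()
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("signal branches must carry positive proportion mass")
    r = mass_b / mass_a
    pi_t = params.pi.copy()
    pi_t[ia] *= r
    pi_t[ib] /= r
    treatment = replace(params, pi=pi_t)
    spec = ScenarioSpec(
        scenario="BS",
        branch_a=A,
        branch_b=B,
        fold_change=r,
        treatment=treatment,
        truth=_truth(tree, ia, ib, r),
        affected_a=tuple(int(k) + 1 for k in ia),
        affected_b=tuple(int(k) + 1 for k in ib),
    )
    return treatment, spec


def _directed_multipliers(
    pi: np.ndarray, idx: np.ndarray, target_mass: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-leaf multipliers m_k > 0, all on the same side of 1, with
    sum(m_k * pi_k) == target_mass; heterogeneity enters through
    m_k - 1 proportional to exp(Uniform(-1, 1))."""
    mass = pi[idx].sum()
    r = target_mass / mass
    if r == 1.0:
        return np.ones(idx.size)
    for _ in range(100):
        spread = np.exp(rng.uniform(-1.0, 1.0, size=idx.size))
        raw = 1.0 + (r - 1.0) * spread
        denom = np.sum(pi[idx] * (raw - 1.0))
        c = (r - 1.0) * mass / denom
        m = 1.0 + c * (raw - 1.0)
        if (m > 0).all():
            return m
    raise RuntimeError("failed to draw positive directed multipliers")


def apply_us(
    params: DMParams, A: int, B: int, tree: Tree, rng: np.random.Generator
) -> tuple[DMParams, ScenarioSpec]:
    """Unbalanced signal: the BS mass swap with heterogeneous per-leaf fold
    changes, all sharing the branch's direction."""
    ia, ib = _leaf_indices(tree, A), _leaf_indices(tree, B)
    mass_a, mass_b = params.pi[ia].sum(), params.pi[ib].sum()
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("signal branches must carry positive proportion mass")
    r = mass_b / mass_a
    m_a = _directed_multipliers(params.pi, ia, mass_b, rng)
    m_b = _directed_multipliers(params.pi, ib, mass_a, rng)
    pi_t = params.pi.copy()
    pi_t[ia] *= m_a
    pi_t[ib] *= m_b
    treatment = replace(params, pi=pi_t)
    multipliers = {int(k) + 1: float(m) for k, m in zip(ia, m_a)}
    multipliers.update({int(k) + 1: float(m) for k, m in zip(ib, m_b)})
    spec = ScenarioSpec(
        scenario="US",
        branch_a=A,
        branch_b=B,
        fold_change=r,
        treatment=treatment,
        truth=_truth(tree, ia, ib, r),
        affected_a=tuple(int(k) + 1 for k in ia),
        affected_b=tuple(int(k) + 1 for k in ib),
        multipliers=multipliers,
    )
    return treatment, spec


def apply_ss(
    params: DMParams,
    A: int,
    B: int,
    tree: Tree,
    rng: np.random.Generator,
    fraction: float = 0.5,
) -> tuple[DMParams, ScenarioSpec]:
    """Sporadic signal: the BS swap restricted to random leaf subsets of
    the given fraction of each branch; unaffected leaves (including those
    inside A and B) keep pi exactly.  fraction = 1 reduces to BS."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ia, ib = _leaf_indices(tree, A), _leaf_indices(tree, B)

    def subset(idx: np.ndarray) -> np.ndarray:
        size = int(round(fraction * idx.size))
        if size < 1:
            raise ValueError(
                f"fraction {fraction} leaves an empty subset on a "
                f"{idx.size}-leaf branch"
            )
        return np.sort(rng.choice(idx, size=size, replace=False))

    sa, sb = subset(ia), subset(ib)
    mass_a, mass_b = params.pi[sa].sum(), params.pi[sb].sum()
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("selected subsets must carry positive proportion mass")
    r = mass_b / mass_a
    pi_t = params.pi.copy()
    pi_t[sa] *= r
    pi_t[sb] /= r
    treatment = replace(params, pi=pi_t)
    spec = ScenarioSpec(
        scenario="SS",
        branch_a=A,
        branch_b=B,
        fold_change=r,
        treatment=treatment,
        truth=_truth(tree, sa, sb, r),
        affected_a=tuple(int(k) + 1 for k in sa),
        affected_b=tuple(int(k) + 1 for k in sb),
    )
    return treatment, spec


def simulate_dataset(
    tree: Tree,
    params: DMParams,
    scenario: ScenarioSpec | None,
    n_control: int,
    n_treatment: int,
    rng: np.random.Generator,
) -> tuple[LeafCountTable, dict[str, int]]:
    """Draw a leaf x sample count table: control samples from ``params``,
    treatment samples from the scenario's modified parameters (or the same
    parameters for a null dataset).  Per-sample depths are resampled with
    replacement from the depth pool."""
    if n_control < 1 or n_treatment < 1:
        raise ValueError("need at least one sample per group")
    treatment = scenario.treatment if scenario is not None else params
    truth = dict(scenario.truth) if scenario is not None else {}
    K = params.pi.size
    if K != tree.n_leaves:
        raise ValueError("params do not match the tree's leaf count")
    depths = rng.choice(params.depths, size=n_control + n_treatment, replace=True)
    cols = {}
    sample_ids = [f"C{j + 1}" for j in range(n_control)] + [
        f"T{j + 1}" for j in range(n_treatment)
    ]
    for j, sid in enumerate(sample_ids):
        p = params if j < n_control else treatment
        cols[sid] = sample_dm(int(depths[j]), p, rng)
    counts = pd.DataFrame(cols, index=tree.leaf_labels)
    counts.index.name = "entity"
    groups = pd.Series(
        ["C"] * n_control + ["T"] * n_treatment, index=sample_ids, name="group"
    )
    return LeafCountTable(counts=counts, groups=groups), truth


def synthetic_tree(K: int, rng: np.random.Generator, prefix: str = "L") -> Tree:
    """Random binary tree over K labeled leaves by sequential uniform
    coalescence (join two uniformly chosen active lineages until one
    remains)."""
    if K < 2:
        raise ValueError(f"need at least 2 leaves, got {K}")
    active = [_Node(label=f"{prefix}{i + 1}") for i in range(K)]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        right = active.pop(j)
        left = active.pop(i)
        active.append(_Node(children=[left, right]))
    return Tree._from_builder(active[0])
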