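"""Per-node differential tests: p-values and estimated directions of change.

Every node of the tree (and every feature in DS mode) receives a raw
(unadjusted) two-sided p-value and a direction sign in {-1, 0, +1} for the
treatment-vs-control contrast.  Two engines are built in:

* :func:`wilcoxon_node_test` — exact/asymptotic Wilcoxon rank-sum on the
  aggregated values (the non-parametric option);
* :func:`nb_glm_node_test` — a negative-binomial log-linear model with a
  group effect and per-sample library-size offsets, tested by likelihood
  ratio (the count-data option).

Any external engine can be plugged in through
:func:`attach_external_stats`, which only requires a (node label, feature,
p, direction) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .aggregation import NodeValueMatrix, validate_groups
from .tree import Tree, TreeError

__all__ = [
    "NodeStats",
    "wilcoxon_node_test",
    "nb_glm_node_test",
    "attach_external_stats",
    "split_groups",
]


@dataclass
class NodeStats:
    """Raw p-values and direction signs per node (and per feature).

    Arrays are indexed by node id (entry 0 unused).  A node with missing p
    (NaN) always has direction 0.
    """

    n_nodes: int
    p: dict[str, np.ndarray] = field(default_factory=dict)
    direction: dict[str, np.ndarray] = field(default_factory=dict)
    effect: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.p)

    def add_feature(self, feature, p, direction, effect=None) -> None:
        p = np.asarray(p, dtype=float)
        direction = np.asarray(direction, dtype=np.int64)
        if p.shape != (self.n_nodes + 1,) or direction.shape != p.shape:
            raise ValueError("stats arrays must have shape (M+1,)")
        ok = ~np.isnan(p)
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if not np.isin(direction, (-1, 0, 1)).all():
            raise ValueError("directions must be in {-1, 0, +1}")
        direction = np.where(ok, direction, 0)
        self.p[feature] = p
        self.direction[feature] = direction
        self.effect[feature] = (
            np.asarray(effect, dtype=float) if effect is not None else np.full(p.shape, np.nan)
        )

    def get(self, feature: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(p, direction) arrays for a feature; feature may be omitted when
        only one is present."""
        if feature is None:
            if len(self.p) != 1:
                raise ValueError("feature must be named when several are present")
            feature = next(iter(self.p))
        return self.p[feature], self.direction[feature]

    def merged(self, other: "NodeStats") -> "NodeStats":
        out = NodeStats(self.n_nodes)
        for src in (self, other):
            for g in src.features:
                out.add_feature(g, src.p[g], src.direction[g], src.effect[g])
        return out

    def to_frame(self, tree: Tree | None = None) -> pd.DataFrame:
        rows = []
        for g in self.features:
            for i in range(1, self.n_nodes + 1):
                rows.append(
                    {
                        "node_id": i,
                        "label": tree.label(i) if tree is not None else "",
                        "feature": g,
                        "p": self.p[g][i],
                        "direction": int(self.direction[g][i]),
                        "effect": self.effect[g][i],
                    }
                )
        return pd.DataFrame(rows)


def split_groups(groups: pd.Series, samples, reference=None):
    """Return (control samples, treatment samples); the reference level
    defaults to the first level in order of appearance."""
    groups = validate_groups(groups, list(samples))
    levels = list(pd.unique(groups))
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    other = levels[1] if levels[0] == reference else levels[0]
    ctrl = [s for s in samples if groups[s] == reference]
    trt = [s for s in samples if groups[s] == other]
    return ctrl, trt


def _sign(x: float) -> int:
    if np.isnan(x) or x == 0:
        return 0
    return 1 if x > 0 else -1


def wilcoxon_node_test(
    values: NodeValueMatrix,
    groups: pd.Series,
    normalize: bool = False,
    reference=None,
) -> NodeStats:
    """Two-sided Wilcoxon rank-sum test at every node.

    The exact null distribution is used when both groups have <= 10
    non-missing samples and no ties occur; otherwise the normal
    approximation with tie correction.  Direction is the sign of
    (treatment mean - control mean); with ``normalize=True`` the values are
    first divided by per-sample library sizes (root-row totals), the natural
    choice for relative-abundance testing of aggregated counts.

    Nodes where either group has fewer than 2 non-missing samples get a
    missing p and direction 0.
    """
    ctrl, trt = split_groups(groups, values.samples, reference)
    df = values.values
    if normalize:
        lib = values.library_sizes()
        if (lib <= 0).any():
            raise ValueError("cannot normalize: some samples have zero totals")
        df = df / lib
    M = values.tree.n_nodes
    p = np.full(M + 1, np.nan)
    d = np.zeros(M + 1, dtype=np.int64)
    eff = np.full(M + 1, np.nan)
    xc_all = df[ctrl].to_numpy()
    xt_all = df[trt].to_numpy()
    for i in range(1, M + 1):
        x = xc_all[i - 1]
        y = xt_all[i - 1]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if x.size < 2 or y.size < 2:
            continue
        diff = y.mean() - x.mean()
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            p[i] = 1.0
            d[i] = 0
            continue
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (x.size <= 10 and y.size <= 10 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(y, x, alternative="two-sided", method=method)
        p[i] = min(1.0, float(res.pvalue))
        d[i] = _sign(diff)
        eff[i] = diff
    stats = NodeStats(M)
    stats.add_feature(values.feature, p, d, eff)
    return stats


# ----------------------------------------------------------------- NB engine


def _nb_loglik(y: np.ndarray, mu: np.ndarray, disp: float) -> float:
    """NB2 log-likelihood (dispersion ``disp``: var = mu + disp * mu^2).

    Entries with mu == 0 contribute 0 when y == 0 and -inf otherwise.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = 0.0
    pos = mu > 0
    if ((~pos) & (y > 0)).any():
        return -np.inf
    y, mu = y[pos], mu[pos]
    if y.size == 0:
        return 0.0
    if disp < 1e-12:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / disp
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + y * np.log(disp * mu / (1.0 + disp * mu))
            - r * np.log1p(disp * mu)
        )
    )


def _fit_nb_rate(y: np.ndarray, lib: np.ndarray, disp: float) -> float:
    """MLE of the rate in ``mu_j = rate * lib_j`` under NB2 with known
    dispersion (Newton on eta = log rate; the log-likelihood is concave)."""
    tot = y.sum()
    if tot == 0:
        return 0.0
    eta = np.log(tot / lib.sum())
    for _ in range(100):
        mu = np.exp(eta) * lib
        score = np.sum((y - mu) / (1.0 + disp * mu))
        info = np.sum(mu * (1.0 + disp * y) / (1.0 + disp * mu) ** 2)
        if info <= 0:
            break
        step = score / info
        eta += np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-12:
            break
    return float(np.exp(eta))


def _moment_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion, floored at 1e-8."""
    pos = mu > 0
    if pos.sum() < 2:
        return 1e-8
    num = np.sum((y[pos] - mu[pos]) ** 2 - mu[pos])
    den = np.sum(mu[pos] ** 2)
    if den <= 0:
        return 1e-8
    return float(np.clip(num / den, 1e-8, 1e3))


_DISP_FLOOR = 1e-8
_DISP_GRID = np.exp(np.linspace(np.log(1e-6), np.log(50.0), 30))


def _fit_rates(Y: np.ndarray, lib: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Row-wise MLE of the rate in ``mu_ij = rate_i * lib_j`` under NB2 with
    known per-row dispersion (vectorized Newton on eta = log rate; the
    log-likelihood is concave in eta).  All-zero rows get rate 0."""
    tot = Y.sum(axis=1)
    ok = tot > 0
    rates = np.zeros(Y.shape[0])
    if not ok.any():
        return rates
    e = np.log(tot[ok] / lib.sum())
    Yo = Y[ok]
    d = disp[ok][:, None]
    for _ in range(100):
        mu = np.exp(e)[:, None] * lib
        score = ((Yo - mu) / (1.0 + d * mu)).sum(axis=1)
        info = (mu * (1.0 + d * Yo) / (1.0 + d * mu) ** 2).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-300), -5.0, 5.0)
        e += step
        if np.max(np.abs(step)) < 1e-12:
            break
    rates[ok] = np.exp(e)
    return rates


def _nb_loglik_rows(Y: np.ndarray, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood; mu == 0 entries contribute 0 when the
    count is 0 and -inf otherwise."""
    d = disp[:, None]
    r = 1.0 / d
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (
            gammaln(Y + r)
            - gammaln(r)
            - gammaln(Y + 1)
            + Y * np.log(d * mu / (1.0 + d * mu))
            - r * np.log1p(d * mu)
        )
    term = np.where(mu > 0, term, np.where(Y > 0, -np.inf, 0.0))
    return term.sum(axis=1)


def _apl_rows(Y: np.ndarray, libs: list[np.ndarray], splits: list[np.ndarray], a: float) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of dispersion ``a`` per row,
    profiling out the group means of the two-group model."""
    n = Y.shape[0]
    av = np.full(n, a)
    out = np.zeros(n)
    for cols, lib in zip(splits, libs):
        Yg = Y[:, cols]
        rates = _fit_rates(Yg, lib, av)
        mu = rates[:, None] * lib
        out += _nb_loglik_rows(Yg, mu, av)
        w = (mu / (1.0 + a * mu)).sum(axis=1)
        out -= np.where(w > 0, 0.5 * np.log(np.maximum(w, 1e-300)), 0.0)
    return out


def _moderated_dispersions(
    Y: np.ndarray, libs, splits, bin_size: int = 10
) -> np.ndarray:
    """Per-row NB dispersion, moderated across rows.

    Each row's Cox-Reid adjusted profile likelihood is evaluated on a fixed
    dispersion grid; rows are binned by overall rate (dispersion trends with
    abundance) and each row receives the larger of its own profile-MLE and
    its bin's consensus MLE.  Taking the maximum guards against the
    dispersion underestimation that makes small-sample likelihood-ratio
    tests anticonservative; the cost is a mildly conservative tail.
    """
    n = Y.shape[0]
    apl = np.stack([_apl_rows(Y, libs, splits, a) for a in _DISP_GRID], axis=1)
    ok = Y.sum(axis=1) > 0
    disp = np.full(n, _DISP_FLOOR)
    idx = np.where(ok)[0]
    if idx.size == 0:
        return disp
    lib_total = sum(l.sum() for l in libs)
    rate = Y.sum(axis=1) / lib_total
    order = idx[np.argsort(rate[idx], kind="stable")]
    n_bins = max(1, idx.size // bin_size)
    for b in np.array_split(order, n_bins):
        trend = _DISP_GRID[int(np.argmax(apl[b].mean(axis=0)))]
        own = _DISP_GRID[np.argmax(apl[b], axis=1)]
        disp[b] = np.maximum(np.maximum(own, trend), _DISP_FLOOR)
    return disp


def nb_glm_node_test(
    values: NodeValueMatrix,
    groups: pd.Series,
    reference=None,
    dispersion: str = "moderated",
) -> NodeStats:
    """Negative-binomial likelihood-ratio test of the group effect per node.

    The model for node ``i`` is ``Y_ij ~ NB(mu_ij, phi_i)`` with
    ``log mu_ij = beta_0 + beta_1 x_j + log L_j`` where ``x_j`` indicates
    the treatment group and ``L_j`` is the leaf-level library size (total
    count) of sample ``j``.  The p-value is the chi-square(1) tail of the
    likelihood ratio for ``beta_1``; the direction is the sign of the fitted
    group log fold change.

    Dispersion ``phi_i`` is estimated per node by Cox-Reid adjusted profile
    likelihood on a grid, moderated by an abundance-binned consensus
    (``dispersion='moderated'``, the default — small-sample raw estimates
    are too noisy to keep the test calibrated); ``dispersion='moment'``
    uses the plain per-node moment estimator instead.  Both are floored at
    1e-8.

    The likelihood-ratio statistic is referred to F(1, J - 2) rather than
    chi-square(1): with the dispersion estimated from J samples the
    chi-square reference is anticonservative in the far tail, which is
    exactly the region multiple-testing corrections act on.  The two
    references agree as J grows.

    Requires sum-aggregated integer counts; a node whose counts are all
    zero gets a missing p and direction 0.
    """
    if values.fun != "sum":
        raise ValueError("nb_glm_node_test requires sum-aggregated counts")
    if dispersion not in ("moderated", "moment"):
        raise ValueError("dispersion must be 'moderated' or 'moment'")
    arr = values.values.to_numpy(dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("nb_glm_node_test requires integer counts")
    ctrl, trt = split_groups(groups, values.samples, reference)
    lib = values.library_sizes()
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"samples with zero library size: {bad}")
    samples = values.samples
    cols_c = np.asarray([samples.index(s) for s in ctrl])
    cols_t = np.asarray([samples.index(s) for s in trt])
    lc = lib.to_numpy(dtype=float)[cols_c]
    lt = lib.to_numpy(dtype=float)[cols_t]
    Y = arr  # (M, J) in node-id order 1..M at rows 0..M-1
    libs = [lc, lt]
    splits = [cols_c, cols_t]

    if dispersion == "moderated":
        disp = _moderated_dispersions(Y, libs, splits)
    else:
        rates_c0 = np.divide(Y[:, cols_c].sum(1), lc.sum())
        rates_t0 = np.divide(Y[:, cols_t].sum(1), lt.sum())
        disp = np.empty(Y.shape[0])
        for i in range(Y.shape[0]):
            mu0 = np.concatenate([rates_c0[i] * lc, rates_t0[i] * lt])
            disp[i] = _moment_dispersion(
                np.concatenate([Y[i, cols_c], Y[i, cols_t]]), mu0
            )

    rate_c = _fit_rates(Y[:, cols_c], lc, disp)
    rate_t = _fit_rates(Y[:, cols_t], lt, disp)
    lib_all = np.concatenate([lc, lt])
    Y_all = np.concatenate([Y[:, cols_c], Y[:, cols_t]], axis=1)
    rate_0 = _fit_rates(Y_all, lib_all, disp)
    lf = _nb_loglik_rows(Y[:, cols_c], rate_c[:, None] * lc, disp) + _nb_loglik_rows(
        Y[:, cols_t], rate_t[:, None] * lt, disp
    )
    ln = _nb_loglik_rows(Y_all, rate_0[:, None] * lib_all, disp)
    stat = np.maximum(0.0, 2.0 * (lf - ln))

    M = values.tree.n_nodes
    p = np.full(M + 1, np.nan)
    d = np.zeros(M + 1, dtype=np.int64)
    eff = np.full(M + 1, np.nan)
    informative = Y.sum(axis=1) > 0
    resid_df = len(ctrl) + len(trt) - 2
    if resid_df < 1:
        informative = np.zeros_like(informative)
    with np.errstate(invalid="ignore"):
        pv = sps.f.sf(stat, 1, max(resid_df, 1))
    for i in range(1, M + 1):
        if not informative[i - 1] or not np.isfinite(stat[i - 1]):
            continue
        p[i] = float(pv[i - 1])
        d[i] = _sign(rate_t[i - 1] - rate_c[i - 1])
        if rate_c[i - 1] > 0 and rate_t[i - 1] > 0:
            eff[i] = float(np.log2(rate_t[i - 1] / rate_c[i - 1]))
    stats = NodeStats(M)
    stats.add_feature(values.feature, p, d, eff)
    return stats


def attach_external_stats(tree: Tree, table: pd.DataFrame) -> NodeStats:
    """Build :class:`NodeStats` from an external engine's result table.

    ``table`` needs columns ``label`` (node label), ``p`` and ``direction``,
    plus optional ``feature`` (default ``"stat"``) and ``effect``.  Unlisted
    nodes get missing p (and are therefore never candidate termini).
    """
    table = pd.DataFrame(table)
    for col in ("label", "p", "direction"):
        if col not in table.columns:
            raise ValueError(f"external stats table must have a {col!r} column")
    if "feature" not in table.columns:
        table = table.assign(feature="stat")
    M = tree.n_nodes
    stats = NodeStats(M)
    for g, sub in table.groupby("feature", sort=False):
        p = np.full(M + 1, np.nan)
        d = np.zeros(M + 1, dtype=np.int64)
        eff = np.full(M + 1, np.nan)
        for row in sub.itertuples(index=False):
            i = tree.node_by_label(str(row.label))
            pv = float(row.p)
            if np.isnan(pv):
                continue
            if not 0.0 <= pv <= 1.0:
                raise ValueError(f"p-value out of range for node {row.label!r}: {pv}")
            dv = int(row.direction)
            if dv not in (-1, 0, 1):
                raise ValueError(f"direction must be in {{-1,0,+1}}, got {dv}")
            p[i] = pv
            d[i] = dv
            if hasattr(row, "effect"):
                eff[i] = float(row.effect)
        stats.add_feature(g, p, d, eff)
    return stats
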