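"""Node-level differential tests: Wilcoxon, NB GLM, external stats."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import treeclimber as tc
from treeclimber.node_tests import _fit_rates, _nb_loglik_rows

from conftest import make_counts


def star_tree(k, prefix="L"):
    return tc.parse_newick("(" + ",".join(f"{prefix}{i}" for i in range(k)) + ");")


def two_groups(n_per_group):
    cols = [f"c{j}" for j in range(n_per_group)] + [f"t{j}" for j in range(n_per_group)]
    groups = pd.Series(["C"] * n_per_group + ["T"] * n_per_group, index=cols)
    return cols, groups


def exact_ranksum_p(x, y):
    """Brute-force two-sided rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n)]
    sums = np.asarray(sums)
    mean = sums.mean()
    return np.mean(np.abs(sums - mean) >= abs(obs - mean) - 1e-12)


class TestWilcoxon:
    def test_separated_groups_exact_p(self, toy_tree):
        # C=(1,2,3) vs T=(10,11,12): 2 of the 20 assignments are as extreme
        cols, groups = two_groups(3)
        counts = make_counts(
            toy_tree,
            {"A": [1, 2, 3, 10, 11, 12], "B": [5] * 6, "C": [7] * 6},
            samples=cols,
        )
        nv = tc.aggregate_da(toy_tree, counts)
        stats = tc.wilcoxon_node_test(nv, groups)
        p, d = stats.get()
        assert p[1] == pytest.approx(0.1)
        assert d[1] == 1

    def test_identical_groups(self, toy_tree):
        cols, groups = two_groups(3)
        counts = make_counts(
            toy_tree, {"A": [4] * 6, "B": [1] * 6, "C": [2] * 6}, samples=cols
        )
        stats = tc.wilcoxon_node_test(tc.aggregate_da(toy_tree, counts), groups)
        p, d = stats.get()
        assert p[1] == 1.0 and d[1] == 0

    def test_undersized_group_gives_missing(self, toy_tree):
        cols = ["c1", "t1", "t2", "t3"]
        groups = pd.Series(["C", "T", "T", "T"], index=cols)
        counts = make_counts(
            toy_tree, {"A": [1, 2, 3, 4], "B": [1] * 4, "C": [1] * 4}, samples=cols
        )
        stats = tc.wilcoxon_node_test(tc.aggregate_da(toy_tree, counts), groups)
        p, d = stats.get()
        assert np.isnan(p[1]) and d[1] == 0

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        tree = star_tree(12)
        for n in (3, 5, 8):
            cols, groups = two_groups(n)
            vals = rng.normal(size=(12, 2 * n))  # continuous => no ties
            counts = pd.DataFrame(vals, index=tree.leaf_labels, columns=cols)
            stats = tc.wilcoxon_node_test(
                tc.aggregate_da(tree, counts, fun="mean"), groups
            )
            p, _ = stats.get()
            for i in range(1, 13):
                expected = exact_ranksum_p(vals[i - 1, :n], vals[i - 1, n:])
                assert p[i] == pytest.approx(expected, abs=1e-10)

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(3)
        tree = star_tree(20)
        cols, groups = two_groups(6)
        counts = pd.DataFrame(
            rng.normal(size=(20, 12)), index=tree.leaf_labels, columns=cols
        )
        nv = tc.aggregate_da(tree, counts, fun="mean")
        a = tc.wilcoxon_node_test(nv, groups, reference="C")
        b = tc.wilcoxon_node_test(nv, groups, reference="T")
        pa, da = a.get()
        pb, db = b.get()
        assert np.allclose(pa[1:], pb[1:], equal_nan=True)
        assert (da[1:] == -db[1:]).all()

    def test_null_pvalues_super_uniform(self):
        # exact rank-sum p-values are discrete, hence conservative:
        # P(p <= x) <= x (+ binomial noise) at every x
        rng = np.random.default_rng(8)
        tree = star_tree(1000)
        cols, groups = two_groups(10)
        counts = pd.DataFrame(
            rng.normal(100, 10, size=(1000, 20)), index=tree.leaf_labels, columns=cols
        )
        stats = tc.wilcoxon_node_test(tc.aggregate_da(tree, counts, fun="mean"), groups)
        p, _ = stats.get()
        lp = p[1:]
        for x in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = (lp <= x).mean()
            assert frac <= x + 3 * np.sqrt(x * (1 - x) / 1000)


class TestNbGlm:
    def test_strong_signal_detected(self):
        tree = tc.parse_newick("(A,B);")
        cols, groups = two_groups(4)
        # equal offsets: every sample totals 200
        a = [5, 6, 5, 6, 50, 60, 55, 58]
        counts = pd.DataFrame(
            {"A": a, "B": [200 - v for v in a]}, index=cols
        ).T
        stats = tc.nb_glm_node_test(tc.aggregate_da(tree, counts), groups)
        p, d = stats.get()
        assert d[1] == 1
        assert p[1] < 0.01

    def test_all_zero_node_missing(self, toy_tree):
        cols, groups = two_groups(3)
        counts = make_counts(
            toy_tree,
            {"A": [0] * 6, "B": [3, 4, 5, 6, 7, 8], "C": [9] * 6},
            samples=cols,
        )
        stats = tc.nb_glm_node_test(tc.aggregate_da(toy_tree, counts), groups)
        p, d = stats.get()
        assert np.isnan(p[1]) and d[1] == 0
        assert not np.isnan(p[2])

    def test_non_integer_rejected(self, toy_tree):
        cols, groups = two_groups(2)
        counts = make_counts(
            toy_tree, {"A": [1.5] * 4, "B": [1] * 4, "C": [1] * 4}, samples=cols
        )
        with pytest.raises(ValueError, match="integer"):
            tc.nb_glm_node_test(tc.aggregate_da(toy_tree, counts), groups)

    def test_lrt_agrees_with_independent_glm_fit(self):
        """Same model, same dispersion: our Newton/LRT vs statsmodels GLM."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        for _ in range(10):
            J = 8
            disp = float(rng.uniform(0.01, 0.5))
            lib = rng.integers(5000, 20000, size=2 * J).astype(float)
            mu = rng.uniform(0.001, 0.01) * lib
            y = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu)).astype(float)
            dv = np.full(1, disp)
            rc = _fit_rates(y[None, :J], lib[:J], dv)
            rt = _fit_rates(y[None, J:], lib[J:], dv)
            r0 = _fit_rates(y[None, :], lib, dv)
            lf = float(
                _nb_loglik_rows(y[None, :J], rc[:, None] * lib[:J], dv)[0]
                + _nb_loglik_rows(y[None, J:], rt[:, None] * lib[J:], dv)[0]
            )
            ln = float(_nb_loglik_rows(y[None, :], r0[:, None] * lib, dv)[0])
            p_mine = sps.chi2.sf(max(0.0, 2 * (lf - ln)), 1)

            x = np.array([0] * J + [1] * J)
            fam = sm.families.NegativeBinomial(alpha=disp)
            full = sm.GLM(y, sm.add_constant(x), family=fam, offset=np.log(lib)).fit()
            null = sm.GLM(y, np.ones((2 * J, 1)), family=fam, offset=np.log(lib)).fit()
            p_ref = sps.chi2.sf(max(0.0, 2 * (full.llf - null.llf)), 1)
            assert p_mine == pytest.approx(p_ref, abs=1e-6)

    def test_null_pvalues_approximately_uniform(self):
        """Null NB counts at 2000 nodes: p-values valid (never anticonservative
        at the cutoffs that drive FDR) and close to uniform overall; the
        dispersion moderation is allowed a small conservative tilt."""
        rng = np.random.default_rng(6)
        tree = star_tree(1000)
        cols, groups = two_groups(10)
        ps = []
        for rep in range(2):
            lib = rng.integers(10_000, 50_001, size=20)
            disp = 0.5  # dispersion of leaf counts around mean rate
            mu = rng.uniform(0.0005, 0.002, size=1000)[:, None] * lib
            y = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu))
            counts = pd.DataFrame(y, index=tree.leaf_labels, columns=cols)
            stats = tc.nb_glm_node_test(tc.aggregate_da(tree, counts), groups)
            p, _ = stats.get()
            lp = p[1:1001]
            ps.append(lp[~np.isnan(lp)])
        ps = np.concatenate(ps)
        assert ps.size >= 1900
        for x in (0.01, 0.05, 0.1):
            assert (ps <= x).mean() <= x + 3 * np.sqrt(x * (1 - x) / ps.size)
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.array([(ps <= x).mean() for x in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.06

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(4)
        tree = star_tree(30)
        cols, groups = two_groups(5)
        counts = pd.DataFrame(
            rng.poisson(40, size=(30, 10)), index=tree.leaf_labels, columns=cols
        )
        nv = tc.aggregate_da(tree, counts)
        a = tc.nb_glm_node_test(nv, groups, reference="C")
        b = tc.nb_glm_node_test(nv, groups, reference="T")
        pa, da = a.get()
        pb, db = b.get()
        assert np.allclose(pa[1:], pb[1:], equal_nan=True, atol=1e-8)
        assert (da[1:] == -db[1:]).all()


class TestExternalStats:
    def test_full_table_pass_through(self, toy_tree):
        table = pd.DataFrame(
            {
                "label": ["A", "B", "C", "node_4", "node_5"],
                "p": [0.1, 0.2, 0.3, 0.01, 0.5],
                "direction": [1, -1, 0, 1, 1],
            }
        )
        stats = tc.attach_external_stats(toy_tree, table)
        p, d = stats.get()
        assert p[4] == 0.01 and d[4] == 1
        assert not np.isnan(p[1:6]).any()

    def test_out_of_range_p_rejected(self, toy_tree):
        table = pd.DataFrame({"label": ["A"], "p": [1.2], "direction": [1]})
        with pytest.raises(ValueError, match="out of range"):
            tc.attach_external_stats(toy_tree, table)

    def test_unknown_label_rejected(self, toy_tree):
        table = pd.DataFrame({"label": ["nope"], "p": [0.5], "direction": [0]})
        with pytest.raises(tc.TreeError):
            tc.attach_external_stats(toy_tree, table)

    def test_leaves_only_keeps_internal_nodes_unselectable(self, toy_tree):
        table = pd.DataFrame(
            {"label": ["A", "B", "C"], "p": [0.001, 0.001, 0.001], "direction": [1, 1, 1]}
        )
        stats = tc.attach_external_stats(toy_tree, table)
        cand = tc.propose_candidate(toy_tree, stats, t=0.5)
        # internal nodes lack p, so the climb must fall through to leaves
        assert cand.termini == (1, 2, 3)
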