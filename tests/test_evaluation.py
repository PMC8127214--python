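"""BH correction, candidate evaluation, the t bound and selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import treeclimber as tc
from treeclimber.evaluation import CandidateEvaluation

from conftest import make_counts, stats_from_dict


def brute_force_bh(p):
    """Step-up from the definition: adj_i = min over j with p_(j) >= p_(i)
    of p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(1.0, running)
    return adj


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(tc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert tc.bh_adjust([0.04]) == pytest.approx([0.04])

    def test_all_ones(self):
        adj = tc.bh_adjust([1.0, 1.0, 1.0])
        assert (adj == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tc.bh_adjust([0.5, 1.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 40))
    def test_agrees_with_brute_force_and_statsmodels(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=n)
        mine = tc.bh_adjust(p)
        assert np.allclose(mine, brute_force_bh(p))
        sm = pytest.importorskip("statsmodels.stats.multitest")
        assert np.allclose(mine, sm.multipletests(p, method="fdr_bh")[1])


class TestTUpper:
    def test_formula(self):
        assert tc.t_upper(0.05, 3) == pytest.approx(0.2)

    def test_no_clustering_forces_leaf_level(self):
        assert tc.t_upper(0.05, 1) == 0.0

    def test_clipped_at_one(self):
        assert tc.t_upper(0.5, 100) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tc.t_upper(0.05, 0.5)
        with pytest.raises(ValueError):
            tc.t_upper(0.0, 2)


class TestEvaluateCandidate:
    def test_two_rejected_branches(self, two_branch_tree):
        tree = two_branch_tree
        n4 = tree.node_by_label("node_11")
        n6 = tree.node_by_label("node_12")
        stats = stats_from_dict(tree, {n4: 0.001, n6: 0.002}, {n4: 1, n6: -1})
        cand = tc.Candidate(t=0.1, termini=(n4, n6))
        ev = tc.evaluate_candidate(cand, stats, tree, alpha=0.05)
        assert (ev.m, ev.R, ev.s, ev.l, ev.R_L) == (2, 2, 2, 10, 10)
        assert ev.r_hat == pytest.approx(5.0)
        assert ev.t_max == pytest.approx(2 * 0.05 * 4)
        assert ev.admissible

    def test_no_rejections_only_leaf_level_admissible(self, two_branch_tree):
        tree = two_branch_tree
        stats = stats_from_dict(
            tree, {i: 0.9 for i in range(1, tree.n_nodes + 1)},
            {i: 1 for i in range(1, tree.n_nodes + 1)},
        )
        ev = tc.evaluate_candidate(
            tc.Candidate(t=0.3, termini=tuple(tree.leaves)), stats, tree, alpha=0.05
        )
        assert ev.s == 0 and ev.r_hat == 1.0 and not ev.admissible
        ev0 = tc.evaluate_candidate(
            tc.Candidate(t=0.0, termini=tuple(tree.leaves)), stats, tree, alpha=0.05
        )
        assert ev0.admissible

    def test_leaf_level_all_rejected_has_unit_branch_size(self, toy_tree):
        stats = stats_from_dict(
            toy_tree, {1: 1e-4, 2: 1e-4, 3: 1e-4}, {1: 1, 2: 1, 3: 1}
        )
        ev = tc.evaluate_candidate(
            tc.Candidate(t=0.0, termini=(1, 2, 3)), stats, toy_tree, alpha=0.05
        )
        assert (ev.s, ev.l) == (3, 3)
        assert ev.r_hat == 1.0


def _eval_from_rejections(tree, t, rejected_nodes, alpha=0.05):
    leaves = set()
    for i in rejected_nodes:
        leaves |= tree.descendant_leaves(i)
    s = len(rejected_nodes)
    l = len(leaves)
    r_hat = max(1.0, l / s) if s else 1.0
    return CandidateEvaluation(
        candidate=tc.Candidate(t=t, termini=tuple(sorted(rejected_nodes)) or (1,)),
        alpha=alpha,
        m=s,
        R=s,
        R_L=l,
        s=s,
        l=l,
        r_hat=r_hat,
        t_max=tc.t_upper(alpha, r_hat),
        admissible=True,
        rejected={"abundance": tuple(sorted(rejected_nodes))},
    )


class TestSelectCandidate:
    @pytest.fixture
    def cherries(self):
        return tc.parse_newick("((A,B),(C,D),(E,F),G);")

    def test_fewest_nodes_wins_at_equal_leaves(self, cherries):
        t = cherries
        p1, p2, p3 = (t.node_by_label(f"node_{i}") for i in (8, 9, 10))
        # both cover 6 leaves; the 3-node candidate must win
        e_fine = _eval_from_rejections(t, 0.05, [p1, p2, 5, 6])
        e_coarse = _eval_from_rejections(t, 0.1, [p1, p2, p3])
        sel = tc.select_candidate([e_fine, e_coarse], t)
        assert sel.candidate is e_coarse.candidate
        assert sel.rejected_leaf_labels == frozenset("ABCDEF")

    def test_more_leaves_beats_fewer_nodes(self, cherries):
        t = cherries
        p1, p2 = t.node_by_label("node_8"), t.node_by_label("node_9")
        e_many = _eval_from_rejections(t, 0.2, [p1, p2, 5, 6, 7])  # 7 leaves, 5 nodes
        e_few = _eval_from_rejections(t, 0.1, [p1, p2])  # 4 leaves, 2 nodes
        sel = tc.select_candidate([e_many, e_few], t)
        assert sel.candidate is e_many.candidate

    def test_inadmissible_candidates_are_discarded_first(self, cherries):
        t = cherries
        p1 = t.node_by_label("node_8")
        e_big = _eval_from_rejections(t, 0.9, [p1, t.node_by_label("node_9")])
        e_big.admissible = False
        e_small = _eval_from_rejections(t, 0.0, [1])
        sel = tc.select_candidate([e_big, e_small], t)
        assert sel.candidate is e_small.candidate

    def test_order_invariance(self, cherries):
        t = cherries
        evs = [
            _eval_from_rejections(t, tv, nodes)
            for tv, nodes in [
                (0.0, [1, 2]),
                (0.05, [t.node_by_label("node_8")]),
                (0.1, [t.node_by_label("node_8"), 5]),
            ]
        ]
        winners = {
            tc.select_candidate(list(perm), t).candidate.t
            for perm in itertools.permutations(evs)
        }
        assert len(winners) == 1

    def test_empty_evaluations_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            tc.select_candidate([], toy_tree)


class TestTreeclimbRun:
    def _bs_dataset(self, seed=7, k=60, n=10):
        rng = np.random.default_rng(seed)
        tree = tc.synthetic_tree(k, rng)
        params = tc.synthetic_params(
            k, theta=0.02, rng=rng, labels=tuple(tree.leaf_labels)
        )
        A, B = tc.pick_signal_branches(tree, params, rng, min_leaves=4, max_leaves=8)
        _, spec = tc.apply_bs(params, A, B, tree)
        table, truth = tc.simulate_dataset(tree, params, spec, n, n, rng)
        return tree, table, truth, spec

    def test_coherent_branch_found_as_branch_not_leaves(self):
        # with coherent branch signal the winner should reject at least one
        # internal node and recover most truth leaves
        for seed in (7, 8, 9):
            tree, table, truth, spec = self._bs_dataset(seed=seed)
            if abs(np.log(spec.fold_change)) < 0.7:
                continue  # weak swap; skip uninformative draws
            res, _ = tc.treeclimb_run(tree, counts=table, groups=table.groups)
            conf = tc.leaf_confusion(res, truth, tree)
            rejected = set().union(*res.rejected.values()) if res.rejected else set()
            assert any(not tree.is_leaf(i) for i in rejected)
            assert conf.tpr >= 0.6
            assert conf.fdr <= 0.2
            break
        else:
            pytest.skip("no strong-signal draw among the tried seeds")

    def test_null_data_rejects_nothing(self):
        rng = np.random.default_rng(11)
        tree = tc.synthetic_tree(50, rng)
        params = tc.synthetic_params(50, theta=0.02, rng=rng, labels=tuple(tree.leaf_labels))
        table, truth = tc.simulate_dataset(tree, params, None, 10, 10, rng)
        res, _ = tc.treeclimb_run(tree, counts=table, groups=table.groups, alpha=0.05)
        assert len(res.rejected_leaves) == 0

    def test_ds_features_stop_at_different_branches(self):
        rng = np.random.default_rng(5)
        tree = tc.parse_newick("((A,B),(C,D));")
        samples = [f"c{j}" for j in range(6)] + [f"t{j}" for j in range(6)]
        groups = pd.Series(["C"] * 6 + ["T"] * 6, index=samples)
        rows = []
        for sid in samples:
            treated = sid.startswith("t")
            for leaf in "ABCD":
                for c in range(15):
                    g1 = rng.normal(3.0 if (treated and leaf in "AB") else 0.0, 1.0)
                    g2 = rng.normal(3.0 if (treated and leaf in "CD") else 0.0, 1.0)
                    rows.append((f"{sid}_{leaf}_{c}", leaf, sid, g1, g2))
        cells = tc.CellTable(
            cells=pd.DataFrame(
                rows, columns=["cell", "leaf", "sample", "g1", "g2"]
            ).set_index("cell"),
            groups=groups,
        )
        res, stats = tc.treeclimb_run(tree, cells=cells, groups=groups, alpha=0.05)
        ab = tree.node_by_label("node_5")
        cd = tree.node_by_label("node_6")
        g1_leaves = set().union(
            *(tree.descendant_leaves(i) for i in res.rejected.get("g1", ()))
        )
        g2_leaves = set().union(
            *(tree.descendant_leaves(i) for i in res.rejected.get("g2", ()))
        )
        assert g1_leaves == tree.descendant_leaves(ab)
        assert g2_leaves == tree.descendant_leaves(cd)

    def test_results_and_evaluation_tables(self, toy_tree):
        cols = [f"c{j}" for j in range(4)] + [f"t{j}" for j in range(4)]
        groups = pd.Series(["C"] * 4 + ["T"] * 4, index=cols)
        rng = np.random.default_rng(0)
        counts = make_counts(
            toy_tree,
            {lab: rng.poisson(50, 8) for lab in "ABC"},
            samples=cols,
        )
        res, stats = tc.treeclimb_run(toy_tree, counts=counts, groups=groups)
        table = res.table()
        assert {"t", "m", "R", "R_L", "admissible", "selected"} <= set(table.columns)
        assert len(table) == 25
        assert table["selected"].sum() >= 1
        frame = res.results_frame(stats, toy_tree)
        assert list(frame.columns)[:3] == ["feature", "node_id", "label"]
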