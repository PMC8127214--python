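# treeclimber

Tree-aware differential abundance (DA) and differential state (DS) analysis
that pinpoints a **data-driven resolution** on a hierarchy of entities —
a Python implementation of the treeclimbR approach.

## The problem

In microbiome surveys, miRNA profiling or clustered single-cell data, the
measured entities (taxa, sequences, cell subpopulations) come with a rooted
tree describing how they relate.  Testing each leaf separately can miss
weak but *coherent* changes that are spread over a branch; testing only
coarse clades cannot pinpoint which entities actually drive an association.
The right resolution is a property of the data, not of the tree, and may
even differ between features.

## The method

Given a leaf × sample count table (DA) or cell-level feature values (DS),
a rooted tree over the entities, and a two-group sample design:

1. **Aggregate** data to every node: `Y_ij = Σ_{k ∈ b(i)} Y_kj` over the
   descendant leaves `b(i)` (sum for counts; median/mean for intensities).
2. **Test** every node for a group difference, giving a p-value `p_i` and a
   direction `sign_i`.  Built-in engines: a negative-binomial log-linear
   model with library-size offsets and moderated dispersions (counts), and
   the Wilcoxon rank-sum test (anything else).  External engines plug in
   via a (label, p, direction) table.
3. **Propose candidates.**  For a tuning value `t ∈ [0, 1]` each node gets
   `q_k(t) = sign_k · 1(p_k ≤ t)` and each branch the coherence score
   `U_i(t) = |Σ_{k ∈ B(i)} q_k(t)| / |B(i)|` over the branch set `B(i)`
   (the node plus all descendants).  Climbing from the root, each path
   stops at the first node with `U_i(t) = 1` and `p_i < 0.05`, or at the
   leaf.  The termini partition the leaves: one candidate resolution per
   `t`.  With several features, each feature climbs independently and the
   candidates are pooled.
4. **Correct** multiplicity *within* each candidate with Benjamini–Hochberg;
   a rejected internal node rejects all its descendant leaves.
5. **Select.**  From the rejections, estimate the mean signal-branch size
   `r̂ = l/s` (leaves `l` over nodes `s`); a candidate is admissible only
   if `t ≤ 2α(r̂ − 1)`, which keeps the *leaf-level* FDR at the nominal
   `α`.  Among admissible candidates, maximize rejected leaves, then
   minimize rejected nodes.

The package also ships a Dirichlet–multinomial simulator with
branch-located signal scenarios (balanced / unbalanced / sporadic
proportion swaps between two branches, `DM(n_j, α)` with
`α_k = π_k (1−θ)/θ`), and a leaf-level TPR/FDR benchmark loop against
leaf-level BH.

## Worked example

```python
import numpy as np
import treeclimber as tc

rng = np.random.default_rng(8)
tree = tc.synthetic_tree(60, rng)                       # random binary tree
params = tc.synthetic_params(60, theta=0.02, rng=rng,
                             labels=tuple(tree.leaf_labels))
A, B = tc.pick_signal_branches(tree, params, rng, min_leaves=4, max_leaves=8)
_, scenario = tc.apply_bs(params, A, B, tree)           # proportion swap
table, truth = tc.simulate_dataset(tree, params, scenario, 10, 10, rng)

result, stats = tc.treeclimb_run(tree, counts=table,
                                 groups=table.groups, alpha=0.05)
print("selected t =", result.t)
print(result.results_frame(stats, tree).to_string(index=False))
conf = tc.leaf_confusion(result, truth, tree)
print(f"leaf-level TPR = {conf.tpr:.2f}, FDR = {conf.fdr:.2f}")
```

prints

```
selected t = 0.35
  feature  node_id   label        p  adjusted_p  direction  n_descendant_leaves  selected_t
abundance       80 node_80 0.000262    0.006417         -1                    7        0.35
abundance       91 node_91 0.000005    0.000252          1                    4        0.35
leaf-level TPR = 0.92, FDR = 0.00
```

The two rejected nodes are *internal*: the method found the planted signal
branches as branches (one up-, one down-regulated, 11 of the 12 truth
leaves recovered, no false leaf) instead of a scatter of individual
leaves, and reported the resolution (`t = 0.35`) at which it did so.

## Command line

```sh
treeclimber simulate --scenario BS --k 100 --n-per-group 10 --seed 7 --out-dir sim/
treeclimber run-da --counts sim/counts.tsv --tree sim/tree.nwk \
                   --meta sim/metadata.tsv --alpha 0.05 --out-dir run/
treeclimber benchmark --scenario BS --reps 50 --alpha 0.01,0.05,0.1 --seed 1 --out-dir bench/
treeclimber run-ds --cells cells.tsv --tree tree.nwk --meta meta.tsv
```

Every run writes a JSON manifest so it can be reproduced from its output
directory alone.

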