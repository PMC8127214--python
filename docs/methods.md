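# Methods

This note documents the statistical model, the estimators, the numerical
choices, and what the simulation framework does and does not emulate.

## Notation and tree machinery

A rooted tree over `K` leaves has `M` nodes numbered with leaves first
(`1..K`, in order of first appearance) and internal nodes after them in
post-order, so the root is always `M` and `i ≤ K` decides leaf-ness in
O(1).  `b(i)` denotes the descendant leaves of node `i` (a leaf maps to
itself) and `B(i)` the branch set: `i` plus all of its descendants,
internal and leaf.  Multifurcating trees are fully supported — taxonomies
and biogenesis hierarchies are rarely binary.  Newick parsing is delegated
to dendropy; serialization regenerates a string whose re-parse reproduces
topology, labels and branch lengths.  `tree_from_linkage` turns a
dissimilarity matrix into a dendrogram tree via scipy's agglomerative
clustering (complete linkage by default, the conventional choice for
building cluster trees from median marker profiles; configurable).

## Aggregation

DA mode: the value of node `i` in sample `j` is the sum (default), mean or
median of its descendant leaves' values.  With sums, the root row is the
per-sample library size and the tree is additive (each internal node
equals the sum of its children), which the suite asserts.

DS mode: the value of feature `g` at node `i` in sample `j` pools all
cells of sample `j` assigned to leaves in `b(i)`; the default is the
median, the usual summary for transformed marker intensities.  A
node × sample combination with no cells is *missing*, is excluded from
testing, and can therefore never be rejected — we do not impute.  Cell
counts per node × sample are exposed so callers can apply their own
weighting; values are not reweighted by cell number.

## Node-level tests

Both engines return a raw two-sided p-value and a direction in
{−1, 0, +1} per node (direction 0 whenever p is missing or the group
difference is exactly zero; such nodes never support a coherent branch).

**Wilcoxon rank-sum** — exact null distribution when both groups have at
most 10 non-missing samples and no ties; normal approximation with tie
correction otherwise.  Direction is the sign of the difference of group
means (stable at small n; medians are an obvious alternative but ties at
small n make them noisier).  With `normalize=True` values are divided by
per-sample library sizes first — the right scale for testing relative
abundance of aggregated counts.  A node needs at least 2 non-missing
samples per group, else its p is missing.

**Negative-binomial LRT** — per node `i`, `Y_ij ~ NB(mu_ij, phi_i)` with
`log mu_ij = beta_0 + beta_1 x_j + log L_j`, `x_j` the treatment
indicator, `L_j` the leaf-level library size.  The group effect is tested
by likelihood ratio; direction is the sign of the fitted log fold change.
Two numerical points matter at realistic sample sizes (10 per group):

* *Dispersion moderation.*  A per-node dispersion estimate from 20
  samples is far too noisy: plugging raw moment estimates into the LRT
  made a quarter of null leaf p-values fall below 0.05 in our
  Dirichlet–multinomial null simulations.  The default estimator
  evaluates each node's Cox-Reid adjusted profile likelihood on a fixed
  30-point log-spaced grid (1e−6..50), bins nodes by overall abundance
  (dispersion trends strongly with abundance in compositional count
  data), and assigns each node the **maximum** of its own profile-MLE and
  its bin's consensus MLE, floored at 1e−8.  Taking the maximum guards
  against underestimation — the failure mode that destroys error control —
  at the price of a mildly conservative mid-range.  A plain per-node
  moment estimator remains available (`dispersion="moment"`).
* *F reference.*  The LR statistic is referred to `F(1, J−2)` rather than
  `chi-square(1)`.  With an estimated dispersion the chi-square reference
  stays ~1.3–1.5× inflated in the far tail (p ≈ 5·10⁻⁴) — precisely the
  region a BH correction over a hundred leaves acts on — and that residual
  inflation showed up as benchmark FDR above nominal at some simulation
  seeds.  The F reference removes it; the two references coincide as J
  grows.

Under both engines, swapping the group labels flips every non-zero
direction and leaves p-values unchanged (asserted).  Any external engine
(e.g. a count model with covariates) can replace the built-ins through
`attach_external_stats`.

## Candidate proposal

For tuning value `t ∈ [0, 1]`:

    q_k(t) = sign_k · 1(p_k ≤ t)        (0 if p_k missing)
    U_i(t) = | Σ_{k ∈ B(i)} q_k(t) | / n_B,   n_B = |B(i)|

`U_i(t) = 1` exactly when every node of the branch is significant at `t`
with one shared non-zero direction; the check is done in integer
arithmetic (|Σq| = n_B), so there is no floating-point ambiguity.  All
nodes in `B(i)` are weighted equally, internal and leaf alike, and nodes
with missing p count toward `n_B` with q = 0 by default (conservative:
pushes U below 1; `count_missing=False` drops them from `n_B` instead).

The climb starts at the root and moves toward the leaves; each path stops
at the first node with `U_i(t) = 1` **and** `p_i < 0.05`, or at the leaf.
The first-on-the-path rule resolves ties between a qualifying node and a
qualifying descendant in favour of the shallower node.  The 0.05
admission threshold is a fixed constant of the method (configurable as
`node_p_threshold`): without it, a signal-free branch whose leaves happen
to share a direction would be represented by its internal node at high
`t`; with it, the probability of representing a null three-leaf branch by
its internal node is 1/4 · 0.05 ≈ 0.0125 (all three leaf signs agree, and
the internal p clears the threshold) — the acceptance script reproduces
this by simulation.  The stop-rule inequality is strict (`p_i < 0.05`)
while the indicator in q is non-strict (`p_k ≤ t`).  Nodes with missing p
are never termini; leaves always are when reached, so the termini of a
candidate always partition the leaf set.

The default exploration grid is {0, 0.01, 0.02, 0.03, 0.04} ∪ {0.05,
0.10, …, 1.00} — 25 values, finer near 0 because weak-signal selections
concentrate there.  `t = 0` yields the leaf-level candidate (testing
without a tree).  In DS mode every feature climbs the tree independently
and the per-feature candidates at a common `t` are pooled into a global
candidate; per-feature terminus lists stay non-nested, while the pooled
node set may nest across features.

## Evaluation and selection

Each candidate's hypothesis list — its terminus nodes, or (feature, node)
pairs for pooled candidates — is BH-corrected jointly, which controls the
global FDR across features rather than per-feature.  A candidate node
with a missing p (an all-zero leaf, say) is excluded from the list and
cannot be rejected.  Rejecting an internal node rejects all of its
descendant leaves.

From the rejected nodes: `s` = number of distinct rejected nodes, `l` =
number of distinct descendant leaves of rejected nodes, and the mean
signal-branch size `r̂ = l/s` (defined as 1 when s = 0, and clamped below
at 1 — a pooled candidate in which several features reject nested nodes
could otherwise push `l/s` under 1, which has no interpretation as a
branch size).  A candidate generated at `t` is admissible iff
`t ≤ 2α(r̂ − 1)`; at `r̂ = 1` only `t = 0` survives: when signals do not
cluster on the tree the leaf level must be used, and the procedure
reduces to leaf-level BH.  The bound is evaluated with each candidate's
own `r̂`; no global iteration.

Selection among admissible candidates: maximize rejected leaves `R_L`
(power), break ties by fewest rejected nodes (parsimony of
interpretation), then by smallest `t` (closest to the leaf level; the
remaining tie is otherwise arbitrary).  The `t = 0` candidate is always
admissible, so a winner always exists.

## Simulation framework

Counts for sample `j` are drawn `x_j ~ DM(n_j, α)` with
`α_k = π_k (1−θ)/θ`: a Dirichlet draw of proportions followed by a
multinomial.  `θ → 0` is the multinomial limit (handled explicitly).
Depths `n_j` are resampled with replacement from a depth pool.  Defaults
for fully synthetic data: `π` from a symmetric Dirichlet(1) over the
leaves, `θ = 0.02` (a typical overdispersion for 16S surveys), depth pool
uniform on 10,000–50,000 — the scale of amplicon sequencing libraries.
`estimate_dm` fits `(π, θ)` from real counts by maximizing the DM
likelihood over log α (L-BFGS-B, moment-estimator start, convergence at
1e−8 on the log-likelihood, `θ̂` clamped to [1e−6, 1−1e−6]); parameter
recovery at K = 50, J = 150 is asserted in the suite.

Group differences modify `π`, never realized counts, so unaffected
entities keep their relative abundance exactly:

* **BS** (balanced): with branches A and B, `r = Σ_B π / Σ_A π`; every
  leaf of A is multiplied by `r`, every leaf of B divided by `r` — an
  exact mass swap, Σπ stays 1 to machine precision.
* **US** (unbalanced): per-leaf multipliers `m_k = 1 + c(r−1)·exp(u_k)`,
  `u_k ~ Uniform(−1, 1)`, with `c > 0` solving the same mass-swap
  constraint.  All multipliers in a branch sit on the same side of 1
  (coherent direction, heterogeneous magnitude).  This construction is
  this package's own; it preserves the BS mass swap by design and is
  isolated behind `ScenarioSpec` so it can be swapped out.
* **SS** (sporadic): the BS swap restricted to random subsets (default
  half) of each branch's leaves; `fraction = 1` reproduces BS exactly,
  which the suite asserts bit-for-bit.

The simulator emulates overdispersed compositional counts with
branch-coherent signal.  It does **not** emulate taxon-specific zero
inflation, depth-dependent noise, phylogenetic signal in `π`, or
correlation between the tree and the direction of change — so passing
benchmarks here show correct behaviour of the *algorithm* under its own
assumptions (independent directions off the signal branches), not
robustness to every real-data pathology.  In particular, trees built from
the same data being tested ("double dipping", e.g. abundance-correlation
trees) violate the independence assumption and can inflate the FDR; use
independent information (sequence, biogenesis, type markers) to build the
tree.

## Benchmarking

Leaf-level scoring: rejected internal nodes are expanded to their
descendant leaves; TPR = TP/(TP+FN), FDR = FP/max(TP+FP, 1), with FDR
defined 0 for a method that rejects nothing.  The benchmark loop fixes
the tree, the DM parameters and the signal branches once per
configuration (repetitions redraw counts only), derives per-repetition
seeds deterministically from the master seed, and is bit-reproducible.
The bundled comparator is leaf-level BH on the same node statistics;
external methods can be scored by passing their called leaf sets to
`leaf_confusion`.

Problem sizes: the acceptance computations use a 100-leaf tree, 10
samples per group and 50 repetitions (and 100,000 branches for the
stop-rule null probability) — small enough to run in seconds on one core,
large enough that the Monte-Carlo standard errors (reported alongside all
benchmark means) are informative.

## Known limitations

* The NB engine supports a two-group design with library-size offsets
  only; covariates and paired designs need an external engine through
  `attach_external_stats`.
* The moderated dispersion's max() rule trades a little power for
  robustness; p-values are validly but detectably conservative in some
  regimes.
* DS selection counts rejected leaves as the union across features; a
  per-feature count is also reported but does not drive selection.
* Effect sizes are pass-through (sign and log fold change); no shrinkage
  or confidence intervals.
* The admissible-`t` bound `2α(r̂−1)` is used as stated; its empirical
  FDR consequence is what the suite verifies.
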