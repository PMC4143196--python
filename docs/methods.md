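# Methods

## Model

A bipartite graph `(I, B, A)` links `n` objects to `m` attributes through
a non-negative weight matrix `A` (1.0 everywhere for binary data).  The
random walker's transition probability is `P(x → y) = A_xy / s_x`, with
`s_x` the strength (weighted degree) of `x`.  Stacking objects before
attributes gives a right-stochastic `(n+m) × (n+m)` Markov matrix `M`
whose off-diagonal blocks are the row-normalized `A` and `Aᵀ`.

The projection similarity is the stationary rate of two-step `i → b → j`
transits:

    S_ij = v*_i Σ_b P(i → b) P(b → j),

with `v*` the stationary distribution, `v* = v* M`, `Σ v* = 1`.  Because
the walk on a connected undirected graph is reversible with
`v*_x = s_x / (2W)` (`W` = total edge weight), `S` reduces to the closed
form `S_ij = Σ_b A_ib A_jb / (2 W s_b)` and is automatically symmetric.
The implementation computes both expressions and asserts their agreement
on every call; the matrix is then exactly symmetrized to remove
floating-point asymmetry.

### Periodicity

A simple walk on a connected bipartite graph has period 2: the walker
alternates sides, so the distribution `v_t` oscillates and does not
converge pointwise.  Uniqueness of the *fixed point* `v = vM` requires
only irreducibility, which connectivity supplies.  We therefore define
`v*` as that fixed point and run power iteration on the lazy chain
`(I + M)/2` — aperiodic, same fixed point — when an iterative solution is
requested.  Three routes (`closed_form`, `power_iteration`,
`eigenvector`) are exposed and cross-checked in tests; `closed_form` is
the default and is exact.

### Direction convention

Summing both walk directions for a pair would multiply every entry by 2
and change no ranking, prediction, or map; the single-direction form is
used.  Total similarity mass over ordered object pairs (diagonal
included) is `Σ_{i∈I} v*_i = 1/2`, a conservation identity the tests
verify.  The diagonal `S_ii` is computed (it is needed for that identity)
but excluded from all ranking, ROC, and map operations.

## Comparator measures

* **ProbS** `W(i,j) = (1/s_j) Σ_b A_ib A_jb / s_b`.  The leading
  normalizer uses the *target* strength; on the reference fixture this
  gives `W(a1,a2) = 1/4`, and binary-graph columns sum to 1 (the unit of
  resource seeded on `j` is fully redistributed).
* **HeatS** is the exact transpose (normalized by the source strength,
  value 1/6 on the fixture); the shared two-step kernel is bitwise
  symmetrized so the transpose identity holds exactly.
* **Hybrid** replaces the normalizer with `s_i^{1-λ} s_j^{λ}`; `λ = 1`
  is ProbS, `λ = 0` is HeatS, default `λ = 0.5` (the optimal value is
  data-dependent and must be chosen by the user).
* **Jaccard** uses attribute *support sets* (weights ignored), the other
  vector measures use raw weights.
* **Euclidean** similarity is `1/(1 + d)`: bounded, equal to 1 for
  identical vectors, monotone in the distance.  (Only "inversely
  proportional" is standard; this concrete form avoids division by zero.)
* **Pearson** uses population variances; constant rows (an object linked
  equally to every attribute) get similarity 0 with a logged warning
  rather than an error, so batch projection never aborts.

For link prediction and maps, asymmetric matrices are symmetrized by the
mean of the two directed entries, which preserves the conservation
totals.

## Monte-Carlo estimator

`monte_carlo_similarity` simulates one walk of `T` transitions and counts
`C_ij`, the `i → b → j` windows.  The long-run frequency of such a window
per transition is exactly `S_ij`, so `Ŝ = (C + Cᵀ) / (2T)` is consistent
and symmetric; the diagonal window is counted on "both orders", matching
the factor the off-diagonal entries receive.  The estimator is seeded and
bit-reproducible; `T ≥ 10(n+m)` is enforced.  It serves as an independent
stochastic oracle for the analytic similarity.

## Evaluation protocols

**Recommendation (object–attribute edges).**  `probe_split` removes a
uniformly random fraction of edges (default 0.1, i.e. a 90/10 split, the
customary choice for this protocol); similarity is recomputed on the
training graph; each attribute-side user's unlinked objects are scored by
the sum (resource-allocation measures) or mean (vector measures) of their
similarity to the user's training items.  The ranking score `r` of a
held-out edge is its item's rank divided by the candidate-list length;
`<r>` averages over probe edges.  Rank ties take the mean rank of the tie
group, which makes `<r>` independent of tie-ordering for degenerate
scorers; hit rates HR-L use the deterministic lexicographic list order.
Probe edges whose user or item lost all training edges (cold start) are
excluded and counted, not scored as failures.

**Link prediction (object–object edges).**  Every unordered object pair
is labelled positive when its observed weight is `≥ τ` (inclusive;
absent pairs weigh 0) — the universe is all pairs, so zero-similarity
positives remain as poorly ranked positives.  AUC is the Mann–Whitney
statistic with half-credit ties, computed from mid-ranks; the ROC curve
comes from scikit-learn and its trapezoid integral is cross-checked
against the rank formula in tests.  `threshold_sweep` reports one AUC
per `τ`, with single-class thresholds reported as undefined rather than
dropped.

## Network maps

`build_map` runs Kruskal over pairs sorted by descending similarity
(ties: lexicographic pair order, so maps are deterministic), keeps the
maximum spanning tree, then appends remaining pairs in the same order
until the average degree `2E/N` reaches the target (default 3; the last
addition may overshoot by `2/N`, since exact equality is generally
unattainable).  Only strictly positive similarities are candidates —
a negative Pearson score is evidence against a link.  Diagnostics are the
unweighted shortest-path-length histogram and the complementary
cumulative degree distribution `P(degree ≥ k)`.

## Synthetic data

The generators define the test conditions for the whole package:

* `worked_example` — the two-object fixture (degrees 3 and 2, one shared
  attribute of degree 2, `W = 5`) on which every measure has a
  hand-derivable value.
* `uniform_random(n, m, p, seed)` — independent Bernoulli edges, reduced
  to the largest component.
* `powerlaw` — zipf-distributed degree sequences on both sides
  (default exponent 2.5, typical of broad empirical degree
  distributions), balanced to equal stub totals and wired by uniform stub
  matching; multi-edges collapse to binary edges, trading exact degree
  sequences for simplicity, so tests assert distributional (heavy-tail)
  properties rather than exact degrees.
* `planted_blocks(n, m, k, p_in, p_out, seed)` — aligned object and
  attribute blocks with dense within-block wiring (defaults
  `p_in = 0.4`, `p_out = 0.05`, 4 blocks: strong but not trivial
  structure); ground truth is every same-block object pair with weight 1,
  making `τ = 1` the natural threshold.  Isolated nodes are pruned but
  the graph is not component-reduced, since with `p_out = 0` the blocks
  are separate components and dropping them would delete every negative.

What these graphs do *not* emulate: correlated attribute usage, degree
assortativity, weight heteroscedasticity, and the size of real catalogs
(benchmarks run at 50–500 nodes).  Passing tests therefore demonstrate
correctness of the computations and recoverability of planted structure
at those scales, not end-to-end performance on any particular empirical
dataset.

## Numerical choices and limitations

* Default tolerance `1e-12`, power-iteration cap `10^5`; dense linear
  algebra up to 2000 states, sparse above.
* Duplicate edge-list rows are an error, never summed; labels are opaque
  strings; binary files get weight 1.0.
* BPR requires a connected graph (irreducibility).  The CLI reduces
  disconnected inputs to the largest component with a logged warning
  (`--strict` errors instead); size ties go to the component holding the
  lexicographically smallest object label.
* Walks longer than two steps, teleportation, and directed bipartite
  graphs are out of scope, as are additional similarity families.
* All randomized operations take explicit seeds and are bit-reproducible.
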