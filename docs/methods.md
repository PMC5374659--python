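# Methods

This note records the model, the parameter choices, and the design
decisions taken where the published description of each stage left the
details open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The pair walk and its conventions

The correspondence model is a Markov chain over pair states
`(v_q, v_t) ∈ V_Q × V_T`. From a state, let
`S = {(x, y) : x ∈ N(v_q), y ∈ N(v_t), s(x, y) > 0}`.

- If `S ≠ ∅`, the walker moves simultaneously to `(x, y) ∈ S` with
  probability ∝ `w(v_q,x) · w(v_t,y) · s(x,y)`. The product form is a
  design choice: it integrates edge confidence on both networks with
  node (sequence) similarity, and degrades to a pure topology walk when
  `s` is flat on `S`.
- If `S = ∅`, one network is chosen with probability 1/2 and the walker
  moves on it alone, neighbor chosen ∝ edge weight. A coordinate
  without neighbors keeps its position for that half-step — this keeps
  every row stochastic without introducing a restart/teleport term,
  which the model does not specify.

**Simultaneous-visit accounting is arrival-based**: the correspondence
score `c(v_q, v_t)` is the stationary probability flow *entering*
`(v_q, v_t)` through simultaneous moves, i.e. `(π P_sim)` at that
state, where `π` is the stationary distribution and `P_sim` the
simultaneous transition block. An occupancy-based convention (mass at
states whose outgoing move is simultaneous) would differ only on states
that mix incoming modes; arrival-based was chosen because "visiting a
pair simultaneously" is an event attached to the move that reaches the
pair. Σ c ≤ 1 always, with equality exactly when every move is
simultaneous.

**Computation.** The distribution (not a sampled walk) is iterated:
`p ← α p + (1−α) p P` from the uniform distribution over
positive-similarity pairs, with laziness `α = 0.5` to guarantee
aperiodicity (the lazy chain has the same stationary distribution).
Convergence is declared at L1 change < `1e-10` (`csrw.tol`), capped at
10 000 sweeps (`csrw.max_iter`); non-convergence returns the last
iterate flagged, with a warning. On reducible chains the limit depends
on the initialization; this is accepted and not hidden behind a
teleportation term, because the reduced target is usually connected via
pseudo-edges and the initial support is exactly where the similarity
evidence lies.

## Pre-processing

Reduction keeps target nodes with `s(v_q, v_t) > T_h` for some query
node (strictly greater; `T_h = 0` keeps any positive score).
Pseudo-edge insertion is *batched*: component membership is computed
once on the reduced graph and all qualifying cross-component pairs are
added in one pass, so output is independent of insertion order. "High
similarity to a common query node" defaults to *any positive score*
(`preprocess.pseudo_sim_quantile = 0`), the least surprising reading
consistent with `T_h = 0`; a quantile of the positive score
distribution can be configured instead. Pseudo-edges get weight 1.0 and
participate in the walk, conductance, extension and rewards exactly
like real edges.

## Seeding

Normalization `C̄ = ½(J_L C + C J_R)` uses reciprocal row/column sums;
a zero row or column simply contributes nothing. The seed score is
computed in the log domain, `Σ_q log(1 − min(c̄, 1 − 1e-12))`, the clip
avoiding `log 0` for near-perfect correspondences. Although the
selection rule is described as iterative, the score does not change
between picks, so a single ranking is equivalent and is what is
implemented. Ties break by larger column maximum of `C̄`, then
lexicographic node id, making output order-independent.

## Extension and pruning

The working conductance is `φ(H) = cut(H)/internal(H)` — boundary edge
count over internal edge count, `+∞` when there are no internal edges —
the small-subnetwork simplification of the classical
`cut / min(vol(H), vol(H̄))`. The two differ (`vol` as a degree sum
equals `2·internal + cut`, not `internal`); the simplified form is
implemented verbatim as `mode="sequoia"` and used by the pipeline, the
classical one is available as `mode="standard"`. Edge counts ignore
weights: the confidence weights inform the walk, while separability is
a purely structural property here.

Greedy extension accepts the frontier node minimizing φ if
`φ_new ≤ (1 − reduction)·φ_current` (default 5%); any finite value
beats `+∞`. The size cap is inclusive: the subnetwork may reach exactly
`cap_factor · |V_Q|` (default 2×) but not exceed it. Candidate ties
break by stronger (more negative) seed log-score — the selection score
is an arg-min, so "better" means smaller — then lexicographically;
unscored candidates sit at 0, the weakest possible value. A newly
accepted node enters with reward 0 and grants +1 to each adjacent
member. Pruning retains seeds unconditionally and otherwise requires
reward strictly greater than the threshold (default 0, i.e. a node must
interact with at least one later-added node to survive). Connectivity
of the pruned result is not enforced; its provenance map lets callers
inspect components.

The recorded `seeds` of a result are the members of the seed network
(the largest connected component of the induced seed set), since only
those participate in and are protected through the search; the ranked
list that produced them is recoverable from the correspondence scores.

## Synthetic data

`generate_pair` emulates a conserved module embedded in a sparse
background: a connected Erdős–Rényi query (resampled until connected),
an Erdős–Rényi background with mean degree 4 — matching the sparsity of
real PPI networks; a Barabási–Albert option exists for degree-
heterogeneity experiments — an implanted copy of the query with each
node deleted w.p. `p_node_delete`, `⌈p_node_insert·|V_Q|⌉` inserted
nodes wired to the module, each copied edge rewired within the module
w.p. `p_edge_rewire`, and one or more bridge edges (1 + Poisson(1))
attaching the implant to the background. Similarity scores are
truncated normals: homolog pairs at mean 100, sd 20 — a plausible
BLAST bit-score scale; only relative magnitudes matter to the walk —
and spurious non-homolog pairs at rate `spurious_pair_rate` with a
quarter of the homolog mean and sd. A single `numpy` generator seeded
by `rng_seed` drives all sampling, so instances are exactly
reproducible.

Defaults (`query_size=10`, `background_size=300`, perturbation
probabilities 0.1, spurious rate 0.05) describe a moderately perturbed
world. What the generator does **not** emulate: degree-correlated
similarity (paralog families), false-negative interaction dropout in
the *query*, weighted-confidence structure, and sequence-level
evolution. A green recovery test therefore establishes that the
pipeline recovers implanted modules under random perturbation of the
stated kind — not performance on real STRING-scale networks, whose
headline numbers depend on external databases and are out of scope
here.

Inserted nodes receive no homolog similarity, so they survive target
reduction only if they happen to draw a spurious score; this mirrors
the real setting where an inserted protein without sequence homology is
only reachable through its interactions.

## Evaluation

The enrichment machinery is a deliberate stand-in for GO::TermFinder: a
one-sided hypergeometric tail `P(X ≥ k)` over a user-supplied flat
protein→term table with Benjamini–Hochberg FDR across tested terms.
Terms are tested only when their information content (computed against
the full annotated universe, which stands in for the ontology root) is
at least `eval.ic_min = 2` and they overlap the tested set. No ontology
graph is parsed and no ancestor propagation or evidence-code filtering
is performed — apply those upstream when preparing the table. Because
the original tool's internal correction may differ from BH, exact
agreement with externally published hit counts is not claimed. The
most-enriched term breaks ties by smallest q, then largest overlap,
then term id.

## Numerical and degenerate-input choices

- Duplicate edge records collapse to the maximum weight (conservative
  merge of redundant interaction records); self-loops are dropped.
- `φ = +∞` sentinel for edgeless subnetworks; `mode="standard"` returns
  0 when the cut is empty (covers H = whole graph, where both
  definitions are 0/0).
- Empty reduced target or empty walk support raise descriptive errors
  rather than returning empty results.
- All tie-breaks in seeding, component choice and extension are total
  orders ending in lexicographic node id, so a given input and
  configuration produce byte-identical output.

## Known limitations

- The power method inherits the chain's mixing time; nearly-reducible
  targets converge slowly (bounded by `csrw.max_iter`).
- The full pair product space is materialized (sparse); memory is
  O(|V_Q| · |V_T,reduced|) states, fine after homolog reduction but not
  intended for unreduced genome-scale targets.
- Greedy extension is step-optimal, not globally optimal; no annealing
  or lookahead is attempted.
- Matching-based evaluation treats complexes as plain node sets;
  overlapping-module output is not supported.
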