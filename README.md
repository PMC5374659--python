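# sequoia

Query a large protein–protein interaction (PPI) network for the
subnetwork that best matches a small query module from another species.

Cross-species network querying asks: given a protein complex or
functional module `G_Q = (V_Q, E_Q)` from one organism and the PPI
network `G_T = (V_T, E_T)` of another, which target subnetwork is the
conserved counterpart of the query? Topology alone is unreliable —
modules evolve by node insertion, deletion and edge rewiring — and
sequence similarity alone ignores interaction patterns. This package
combines both, and is aimed at computational biologists who want a
deterministic, scriptable querying pipeline plus the standard metrics
to evaluate its output against reference complex sets and functional
annotations.

## Method

1. **Pre-processing.** Target nodes with no query homolog above a
   similarity threshold `T_h` (default 0) are removed. Because this can
   disconnect the target, *pseudo-edges* are inserted between nodes in
   different components that share a high-similarity query node.
2. **Node correspondence (context-sensitive random walk).** A walker
   lives on pair states `(v_q, v_t)`. Where neighbor pairs with
   positive similarity `s(x, y) > 0` exist it steps simultaneously on
   both networks with probability ∝ `w(v_q,x) · w(v_t,y) · s(x,y)`;
   otherwise it steps on one network chosen uniformly — the pair-HMM-like
   mode switch that absorbs inserted/deleted nodes. The long-run rate of
   simultaneous visits to `(v_q, v_t)`, computed by power iteration,
   is the correspondence score `c(v_q, v_t)`, collected in the
   `|V_Q| × |V_T|` matrix **C**.
3. **Seed selection.** **C** is normalized as
   `C̄ = ½ (J_L C + C J_R)` (reciprocal row/column sums on the
   diagonals), and the `N_Q = |V_Q|` target nodes minimizing
   `∏_q (1 − c̄(v_q, v_t))` are selected; the seed network is the
   largest connected component they induce.
4. **Conductance-minimizing extension.** With
   `φ(H) = cut(H) / internal(H)` (boundary edges over internal edges),
   the frontier node minimizing φ is added while it reduces φ by ≥ 5%
   and the subnetwork stays within 2×|V_Q|. Each accepted node grants an
   extension reward of +1 to every adjacent member.
5. **Pruning.** Non-seed nodes whose reward does not exceed 0 are
   removed; seeds are always kept.

Evaluation utilities implement the Jaccard matching score against a
gold-standard complex set (match at ≥ 0.5), term information content
`IC(g) = −log₂(|g|/|root(g)|)` with an IC ≥ 2 informativeness filter, a
one-sided hypergeometric enrichment test with Benjamini–Hochberg FDR
over a flat protein→term table, and hit / FC-hit / SPE classification.

## Worked example

Generate a synthetic instance — a 10-node query implanted, with 10%
node deletion/insertion/edge rewiring and 5% spurious similarity, into
a 300-node background — then query it:

```sh
sequoia synth --seed 3 --out demo
sequoia query --query demo/query.tsv --target demo/target.tsv \
              --sim demo/similarity.tsv --out demo/result.txt
```

which prints

```
query: 10 nodes (10 seeds)
```

and `demo/result.txt` begins

```
query_id        query
seeds   h6,h2,h0,h9,h1,b202,h8,h5,h4,x0
trace   3.5238095238095237
#node   provenance      reward
b202    seed    0
h0      seed    0
...
```

The implanted module at this seed is `{h0, h1, h2, h4, h5, h6, h8, h9,
x0}` (`h*` are surviving homologs, `x0` an inserted node). The result
recovers all nine implanted nodes plus one background node (`b202`),
a Jaccard recovery of 9/10 = 0.9 against the ground truth
(`sequoia.recovery_score`). The `trace` line is the conductance after
each extension step — here the seed network already had conductance
3.52 and no neighbor could cut it by 5%, so no extension step was
accepted. Dotted flags override any default, e.g.
`--extend.reduction 0.10`.

Python API equivalent:

```python
from sequoia import SynthConfig, generate_pair, run_query, recovery_score

query, target, sim, truth = generate_pair(SynthConfig(rng_seed=3))
result = run_query(query, target, sim)
print(len(result.nodes), recovery_score(result, truth))  # 10 0.9
```

## Acceptance script

`scripts/acceptance.py` exercises the full pipeline end to end —
synthetic instance generation, pre-processing, the random walk,
seeding, extension, pruning and recovery scoring — on instances derived
from the given seed, printing per-replicate recovery, and writes its
JSON report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Input formats

- network TSV: `node_a<TAB>node_b[<TAB>weight]`, `#` comments ignored
- similarity TSV: `query_id<TAB>target_id<TAB>score` (BLAST-bit-score-like)
- complexes: GMT-like `name<TAB>member1<TAB>member2…`
- annotations: `protein_id<TAB>term_id`, one pair per line

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
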