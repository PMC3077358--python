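# Methods

## Scope

`netarch` treats an observed network as the newest snapshot of a growth
process in which nodes arrive one at a time, and infers the history by
greedy maximum-likelihood reversal: at each step, compute for every
candidate the likelihood that it was the most recent arrival under the
assumed model, undo the best candidate, and repeat until one node remains.
All graphs are undirected and simple with opaque string labels; algorithms
never read labels (synthetic generators label nodes `n0, n1, …` in arrival
order purely so tests can check ground truth).

## Growth models

**DMC (duplication–mutation with complementarity).** From a connected
two-node seed, each arriving node `v` picks a uniform anchor `u` and copies
all of `u`'s links. For each neighbor `w` of `u`, with probability `q_mod`
exactly one of the pair `(v,w)`, `(u,w)` — fair coin — is deleted; then the
edge `(u,v)` is added with probability `q_con`. A variant deletes one
uniformly random node (and its edges) with probability `q_del` after each
arrival. Histories record every edge change so replay is exact.

**FF (forest fire).** Each arriving node links to a uniform anchor and to
every node burned by a fire spreading from the anchor: each burning node
ignites `x` of its unvisited neighbors, `x ~ Geometric` on `{0,1,…}` with
success probability `1−p` (mean `p/(1−p)`), sampled as
`floor(log U / log p)`; if `x` exceeds the eligible count, all burn.

**PA (linear preferential attachment).** From a `k0`-clique seed
(`k0 = m+1` by default), each arrival links to `m` distinct nodes drawn
sequentially without replacement with probability proportional to current
degree.

**Noise.** `replace_edges(g, f, seed)` removes `round(f·|E|)` uniform
edges and adds the same number of uniform non-edges drawn from the
complement of the *original* graph, so removed edges are never re-added;
if the complement is exhausted the shortfall is reported.

## Reversal likelihoods

**DMC.** Every unordered node pair `(u,v)` is a candidate duplicate pair
with log-likelihood

```
log [ 1/(N−1) · γ(u,v) · (1−q_mod)^|C| · (q_mod/2)^|D| ]
```

where `γ = q_con` if the edge `(u,v)` exists, else `1−q_con`; `C` is the
set of common neighbors and `D` the symmetric difference of neighborhoods,
both excluding `u,v` themselves. The winning pair is merged: a fair coin
picks the removed node, and the kept node inherits the removed node's
other links — links it gains that were absent in the observed snapshot are
the *inferred ancestral edges*. Zero-probability factors map to an
explicit `−inf` sentinel with the `0·(−inf)=0` convention for absent
counts.

**FF.** Every ordered adjacent pair (node `v`, anchor `u`) is a candidate.
Its likelihood is estimated by Monte Carlo: on the graph with `v` absent,
simulate `S` fires from `u` (default `S=100`) and count the fraction whose
burned set equals `N(v)\{u}` exactly. The winner is removed with its
edges; edges are never re-added, so FF reconstructions have no ancestral
edges.

**PA.** Candidates are the minimum-degree nodes; a node's score is
`Σ log(deg(w)−1)` over its neighbors `w` (their degrees one step earlier).
The score is undefined (`−inf`) for isolated nodes or degree-1 neighbors.

Ties are broken uniformly at random from the run's seeded generator. When
no candidate has positive likelihood the engine falls back to a random
removal (flagged, log-likelihood `−inf`); FF fallbacks record a random
neighbor as anchor so reconstructions stay anchor-complete. A `random`
policy (DMC only) merges uniformly random pairs while still recording
their model scores — the null reconstruction for likelihood-ratio
comparisons.

## Incremental score tables

Naively recomputing all candidate scores each step is quadratic per step
and prohibitive. Both engines maintain tables that are provably equal to
from-scratch recomputation (asserted by tests):

- **DMC:** adjacency matrix plus a common-neighbor matrix `A·A`; after
  merging, only columns of the kept node and the removed node's former
  neighbors can change, and they are recomputed with a partial matrix
  product. The constant `−log(N−1)` is factored out of the stored scores
  (it never affects the argmax within a step).
- **FF:** a numba kernel stores per-candidate estimates. A simulation
  aborts the moment it burns a node outside the target set, so an
  estimate depends only on the adjacency of the anchor and the target
  set; after removing node `r`, only candidates `(v′,u′)` with `v′`
  within distance 2 of `r` or `u′` adjacent to `r` can change — the exact
  dirty rule. Each candidate draws from its own RNG substream derived
  from `(run seed, v, u)` via a splitmix64 mix (masked to 63 bits so
  values survive Python↔numba round trips), making cached and uncached
  reversals bit-identical.

## Validation measures

- **Kendall τ** between true and inferred arrival orders, computed by the
  exact tie-free concordance formula `(C−D)/C(n,2)` (scipy's τ-b
  introduces float noise on identical permutations). Random orders → 0.
- **Normalized Spearman footrule** `1 − Σ|σ(v)−σ′(v)| / ⌊n²/2⌋` over
  1-based ranks; identical orders → 1, random orders → 1/3.
- **Anchor trees:** each arrival conceptually splits its anchor's leaf in
  two; forward histories are built bottom-up newest-first with the 2-node
  seed as the final cherry, reverse histories by joining (anchor, removed)
  in removal order. Quality = percentage of the true tree's clades (leaf
  sets under internal nodes, root included, singletons excluded) present
  in the reconstructed tree. After node-deletion runs both orders and
  trees are restricted to extant nodes.
- **Real-network measures** (no ground-truth times): class-based Kendall
  over node pairs in different age classes; the fraction of inferred
  node/anchor pairs sharing a functional annotation (vs the extant-edge
  baseline); shared-annotation fractions of the k newest/oldest extant
  edges under forward replay of a reconstruction, and of inferred
  ancestral edges (vs the non-adjacent-pair baseline); snapshot statistics
  (density, mean clustering, mean shortest path over connected pairs,
  mean k-core number).

## Experiments harness

`run_reversibility` grows `R` networks per condition, optionally perturbs
them (`replace_edges` or the `q_del` variant), reverses each under every
cell of a reverse-parameter grid (DMC default: `{0.1,0.3,…,0.9}²`; FF:
`p ∈ {0.1,…,0.5}`), and scores Kendall, footrule and (when both sides
carry anchors) clade recovery against the truth. "Optimal reverse
parameters" = the cell maximizing a measure's mean. Trial seeds are
`base_seed + trial` so any trial is re-runnable in isolation; per-cell
reversal seeds are derived via `SeedSequence` and kept below 2³¹.
`confusion_matrix` crosses growth models with reversal models (including
heuristics); `parameter_grid_search` ranks reverse-parameter cells for a
single observed network by total reconstruction log-likelihood or by
class-based Kendall.

## Problem sizes and budgets

The shipped studies use 100-node networks — the package's own choice to
keep the full acceptance run under ~20 minutes on one CPU: a DMC reversal
of a dense 100-node graph takes ~40 ms, an FF reversal ~20 ms (sparse) to
~1 s (dense), and the headline experiments total ≈ 8 000 reversals. The
algorithms themselves handle graphs of a few thousand nodes; the DMC
table is O(n²) memory and the FF kernel O(n²) per dirty column scan.

## Limitations

- Greedy reversal commits to one step at a time; it reports a single
  maximum-likelihood-per-step history, not a posterior over histories.
- The FF likelihood is a Monte-Carlo estimate; with `S=100` simulations,
  candidates with true likelihood below ~1/S are indistinguishable from
  impossible, which is the main driver of FF fallback steps.
- PA reversal carries no anchor information, so no anchor trees for PA.
- Published real-data results (protein-interaction and listening-history
  networks) require external datasets; the package exposes the full
  pipeline (edge lists, age-class and annotation tables, class-based
  Kendall, annotation agreement) for user-supplied files but ships no
  data.
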