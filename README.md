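# netarch

Likelihood-based reconstruction of network growth histories ("network
archaeology"). Given only a present-day snapshot of a network that grew one
node at a time, `netarch` infers *when* each node arrived and *which*
existing node it attached to, by repeatedly undoing the single most likely
growth step under an assumed growth model.

## The idea

Many networks grow by local mechanisms: in protein-interaction networks a
gene duplicates and the copy inherits its template's interactions; in
social networks a newcomer befriends one person and then part of that
person's circle. Each mechanism leaves a statistical fingerprint in the
final topology. If we can write down the probability that a given node was
the most recent arrival, we can peel the network backwards step by step,
recovering an arrival order, a sequence of ancestral networks, and — for
duplication-style models — a binary *anchor tree* recording who copied
whom, analogous to a gene phylogeny.

`netarch` implements this program end to end:

- **Forward simulators** for three classic growth models, each returning a
  replayable history: duplication-mutation with complementarity (**DMC**,
  parameters `q_mod`, `q_con`, optional node-deletion rate `q_del`),
  forest fire (**FF**, burn probability `p`), and linear preferential
  attachment (**PA**, `m` edges per arrival). Plus an edge-replacement
  noise model for robustness experiments.
- **Greedy reversal engines** with per-model likelihoods: a closed-form
  duplicate-pair score for DMC, a Monte-Carlo fire-simulation likelihood
  for FF, and a degree-based arrival score for PA. Candidate scores are
  maintained in incrementally updated tables (numpy for DMC, a numba
  kernel for FF), so reversing dense 100-node networks takes milliseconds
  to about a second.
- **Heuristic baselines** (static degree, closeness centrality) to show
  what the likelihood machinery adds.
- **Validation measures**: Kendall tau and normalized Spearman footrule
  between true and inferred arrival orders, anchor-tree clade recovery,
  class-based Kendall tau and annotation-agreement measures for real
  networks where only node age classes or functional labels are known, and
  snapshot statistics (density, clustering, path length, core numbers).
- **An experiments harness** that grows, optionally perturbs, reverses
  over reverse-parameter grids, and reports best-cell means — including a
  growth-model × reversal-model confusion matrix and likelihood-based
  parameter selection for observed networks.

## Worked example

Grow a 100-node DMC network, reverse it, and score the reconstruction:

```python
import netarch as na

params = na.DMCParams(q_mod=0.1, q_con=0.9)
graph, history = na.grow_dmc(100, params, seed=42)
result = na.reverse(graph, "dmc", params, seed=7)

truth, pred = history.arrival_order(), result.arrival_order()
print(na.footrule(truth, pred))
print(na.anchor_similarity(na.build_anchor_tree(history),
                           na.build_anchor_tree(result)))
```

Output:

```
0.4284
53.535353535353536
```

— the inferred arrival order places nodes far better than a random order
(footrule 0.43 vs 0.33 expected at random), and about half of the true
duplication clades are recovered exactly.

The same pipeline from the command line:

```bash
netarch grow --model dmc --n 100 --qmod 0.1 --qcon 0.9 --seed 42 \
    --out-graph g.txt --out-history truth.tsv
netarch reverse --graph g.txt --model dmc --qmod 0.1 --qcon 0.9 --seed 7 \
    --out-history pred.tsv --out-tree pred.nwk
netarch validate --truth-history truth.tsv --predicted-history pred.tsv
```

```
tau	0.1467
footrule	0.4284
anchor	53.54
```

Other commands: `netarch benchmark --config cfg.yaml --out results.csv`
(reversibility grids from a YAML spec), `netarch classtau` (age-class
concordance for real networks), `netarch stats` (snapshot statistics).
Every command takes `--seed` and is bit-reproducible given it.

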