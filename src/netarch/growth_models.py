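"""Forward stochastic network growth simulators.

Three classic growth mechanisms are implemented:

* **DMC** (duplication-mutation with complementarity): a new node copies
  all links of a uniformly chosen anchor; each copied link or its original
  is then deleted with probability ``q_mod`` (fair coin picks which of the
  two), and the node-anchor link is added with probability ``q_con``.
  An optional node-deletion variant removes a uniformly random existing
  node with probability ``q_del`` after each arrival.
* **FF** (forest fire): a new node links to a random anchor, then a fire
  spreads outward: at each burning node the fire picks ``x`` unvisited
  neighbors, ``x`` geometric with mean ``p/(1-p)``, and the new node links
  to every burned node.
* **PA** (linear preferential attachment): starting from a clique, each
  new node links to ``m`` distinct existing nodes drawn with probability
  proportional to degree.

Every simulator returns the final graph plus a :class:`GrowthHistory`
whose replay reproduces the graph exactly; identical seeds give identical
output.  Nodes are labeled ``n0``, ``n1``, ... in arrival order — the
reversal algorithms never look at labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import ForwardEvent, GrowthHistory, LabeledGraph, new_graph

__all__ = [
    "DMCParams",
    "FFParams",
    "PAParams",
    "grow_dmc",
    "grow_ff",
    "grow_pa",
    "replace_edges",
]


@dataclass(frozen=True)
class DMCParams:
    """DMC probabilities: edge modification, anchor connection, node deletion."""

    q_mod: float
    q_con: float
    q_del: float = 0.0

    def __post_init__(self):
        for name in ("q_mod", "q_con", "q_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")


@dataclass(frozen=True)
class FFParams:
    """Forest fire burn probability and reversal simulation count."""

    p: float
    n_sims: int = 100

    def __post_init__(self):
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"burn probability p={self.p} must lie in [0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be a positive integer")


@dataclass(frozen=True)
class PAParams:
    """Edges per arriving node and seed clique size (default m + 1)."""

    m: int
    k0: int | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        k0 = self.seed_size
        if k0 < 2 or k0 < self.m:
            raise ValueError(f"seed clique size k0={k0} must be >= max(2, m)")

    @property
    def seed_size(self) -> int:
        return self.k0 if self.k0 is not None else self.m + 1


def _labels(n: int) -> list[str]:
    return [f"n{i}" for i in range(n)]


def grow_dmc(n: int, params: DMCParams, seed: int) -> tuple[LabeledGraph, GrowthHistory]:
    """Grow an ``n``-arrival DMC network from a connected two-node seed.

    With ``q_del > 0`` the returned graph can have fewer than ``n`` nodes.
    """
    if n < 2:
        raise ValueError("DMC growth needs n >= 2")
    rng = np.random.default_rng(seed)
    g = new_graph([("n0", "n1")])
    events: list[ForwardEvent] = []
    for i in range(2, n):
        v = f"n{i}"
        existing = sorted(g.nodes)
        anchor = existing[rng.integers(len(existing))]
        added: list[tuple[str, str]] = []
        removed: list[tuple[str, str]] = []
        g.add_node(v)
        for w in sorted(g.neighbors(anchor)):
            g.add_edge(v, w)
            added.append((v, w))
            if rng.random() < params.q_mod:
                if rng.random() < 0.5:  # fair coin: lose the copy or the original
                    g.remove_edge(v, w)
                    added.pop()
                else:
                    g.remove_edge(anchor, w)
                    removed.append((anchor, w))
        if rng.random() < params.q_con:
            g.add_edge(anchor, v)
            added.append((anchor, v))
        deleted = None
        if params.q_del > 0 and rng.random() < params.q_del:
            candidates = sorted(g.nodes)
            deleted = candidates[rng.integers(len(candidates))]
            g.remove_node(deleted)
        events.append(ForwardEvent(v, anchor, added, removed, deleted))
    history = GrowthHistory(["n0", "n1"], [("n0", "n1")], events, "dmc",
                            {"q_mod": params.q_mod, "q_con": params.q_con,
                             "q_del": params.q_del})
    return g, history


def _fire_spread(neighbors: dict[str, set], anchor: str, p: float,
                 rng: np.random.Generator, forbidden: str | None = None) -> list[str]:
    """Burned set (excluding the anchor) of one forest-fire spread.

    ``forbidden`` marks a node treated as absent (used by the reversal's
    likelihood simulations).  Spread is breadth-first: at each burning
    node, x ~ Geometric(1-p) on {0,1,...} unvisited neighbors catch fire.
    """
    visited = {anchor}
    if forbidden is not None:
        visited.add(forbidden)
    burned: list[str] = []
    queue = [anchor]
    while queue:
        w = queue.pop(0)
        if p > 0.0:
            # floor(log(U)/log(p)) is Geometric(1-p) on {0,1,2,...}
            x = int(np.log(rng.random()) // np.log(p)) if p > 0 else 0
        else:
            x = 0
        if x <= 0:
            continue
        eligible = sorted(set(neighbors[w]) - visited)
        if x >= len(eligible):
            chosen = eligible
        else:
            chosen = [eligible[j] for j in rng.choice(len(eligible), size=x, replace=False)]
        for c in chosen:
            visited.add(c)
            burned.append(c)
            queue.append(c)
    return burned


def grow_ff(n: int, params: FFParams, seed: int) -> tuple[LabeledGraph, GrowthHistory]:
    """Grow an ``n``-node forest fire network from a connected two-node seed."""
    if n < 2:
        raise ValueError("FF growth needs n >= 2")
    rng = np.random.default_rng(seed)
    g = new_graph([("n0", "n1")])
    events: list[ForwardEvent] = []
    for i in range(2, n):
        v = f"n{i}"
        existing = sorted(g.nodes)
        anchor = existing[rng.integers(len(existing))]
        neighbors = {u: set(g.neighbors(u)) for u in g.nodes}
        burned = _fire_spread(neighbors, anchor, params.p, rng)
        added = [(v, anchor)] + [(v, w) for w in burned]
        g.add_node(v)
        g.add_edges_from(added)
        events.append(ForwardEvent(v, anchor, added, []))
    history = GrowthHistory(["n0", "n1"], [("n0", "n1")], events, "ff",
                            {"p": params.p})
    return g, history


def grow_pa(n: int, params: PAParams, seed: int) -> tuple[LabeledGraph, GrowthHistory]:
    """Grow an ``n``-node linear preferential attachment network.

    Starts from a ``k0``-clique; each arrival draws ``m`` distinct nodes
    sequentially without replacement, probability proportional to degree
    (renormalised over the remaining nodes), and links to all of them.
    """
    k0 = params.seed_size
    if n < k0:
        raise ValueError(f"PA growth needs n >= seed clique size {k0}")
    rng = np.random.default_rng(seed)
    seed_nodes = _labels(k0)
    seed_edges = [(seed_nodes[i], seed_nodes[j])
                  for i in range(k0) for j in range(i + 1, k0)]
    g = new_graph(seed_edges)
    events: list[ForwardEvent] = []
    for i in range(k0, n):
        v = f"n{i}"
        existing = sorted(g.nodes)
        degrees = np.array([g.degree(u) for u in existing], dtype=float)
        targets: list[str] = []
        for _ in range(params.m):
            probs = degrees / degrees.sum()
            j = rng.choice(len(existing), p=probs)
            targets.append(existing[j])
            degrees[j] = 0.0  # without replacement
        added = [(v, t) for t in targets]
        g.add_node(v)
        g.add_edges_from(added)
        events.append(ForwardEvent(v, None, added, []))
    history = GrowthHistory(seed_nodes, seed_edges, events, "pa",
                            {"m": params.m, "k0": k0})
    return g, history


def replace_edges(g: LabeledGraph, fraction: float, seed: int) -> tuple[LabeledGraph, int]:
    """Replace a fraction of edges with uniformly chosen non-edges.

    Removes ``round(fraction * |E|)`` random edges and adds the same number
    of random non-edges, keeping the node set and (when the complement is
    large enough) the edge count.  Returns the perturbed copy and the
    shortfall: the number of replacement edges that could not be added
    because the complement ran out.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = g.copy()
    edges = sorted(tuple(sorted(e)) for e in out.edges)
    k = int(fraction * len(edges) + 0.5)
    if k == 0:
        return out, 0
    to_remove = [edges[j] for j in rng.choice(len(edges), size=k, replace=False)]
    out.remove_edges_from(to_remove)
    # Replacements are drawn from the complement of the *original* graph,
    # so removed edges are never re-added (they are replaced by new edges).
    nodes = sorted(g.nodes)
    non_edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                 if not g.has_edge(a, b)]
    add_count = min(k, len(non_edges))
    if add_count:
        for j in rng.choice(len(non_edges), size=add_count, replace=False):
            out.add_edge(*non_edges[j])
    return out, k - add_count
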