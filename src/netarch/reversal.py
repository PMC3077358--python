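"""Per-model likelihood scores and the greedy single-step reversal engine.

The reversal treats the observed graph as the newest snapshot of a growth
process and repeatedly undoes the single most likely growth step under the
assumed model, until one node remains:

* **DMC** — every unordered node pair is a candidate duplicate pair; its
  score is the log of ``1/(N-1) * gamma(u,v) * (1-q_mod)^|C| * (q_mod/2)^|D|``
  where ``gamma`` is ``q_con`` if the pair is linked else ``1-q_con``,
  ``C`` their common neighbors and ``D`` the symmetric difference of their
  neighborhoods (both excluding the pair itself).  The winning pair is
  merged: a fair coin picks which node is removed, and the kept node gains
  the removed node's other links (these are the inferred ancestral edges).
* **FF** — every ordered adjacent pair (node, anchor) is a candidate; its
  likelihood is estimated by simulating fires from the anchor with the
  node absent and counting exact matches of the burned set with the
  node's other neighbors.  The winner is removed with its edges.
* **PA** — candidates are the minimum-degree nodes; a node's score is the
  sum of ``log(deg - 1)`` over its neighbors (their degrees one step
  earlier).  The winner is removed with its edges.

Ties are broken uniformly at random with the run's seeded generator.  All
candidate scores are kept in incrementally maintained tables; after each
removal only candidates whose score can actually have changed are
recomputed, which is what makes reversal of dense graphs tractable.
"""

from __future__ import annotations

import math

import numpy as np

from . import _ff_kernel
from .graph_core import (
    NEG_INF,
    LabeledGraph,
    ReconstructionResult,
    ReverseEvent,
    validate_graph,
)
from .growth_models import DMCParams, FFParams, PAParams

__all__ = [
    "dmc_pair_score",
    "apply_dmc_merge",
    "ff_anchor_likelihood",
    "pa_node_score",
    "reverse",
    "total_log_likelihood",
    "DMCScoreTable",
]


def _log_or_neginf(x: float) -> float:
    return math.log(x) if x > 0.0 else NEG_INF


# ---------------------------------------------------------------------------
# Reference (per-pair) score functions
# ---------------------------------------------------------------------------


def dmc_pair_score(g: LabeledGraph, u: str, v: str, params: DMCParams) -> float:
    """Log-likelihood that ``(u, v)`` is the most recent duplicate pair.

    Returns the minus-infinity sentinel when any probability factor is
    zero.  Symmetric in ``u`` and ``v``.
    """
    if u not in g or v not in g:
        raise ValueError(f"nodes {u!r}, {v!r} must both be in the graph")
    if u == v:
        raise ValueError("pair score needs two distinct nodes")
    n = g.number_of_nodes()
    nu = set(g.neighbors(u)) - {u, v}
    nv = set(g.neighbors(v)) - {u, v}
    c = len(nu & nv)
    d = len(nu ^ nv)
    gamma = params.q_con if g.has_edge(u, v) else 1.0 - params.q_con
    score = -math.log(n - 1) + _log_or_neginf(gamma)
    if c:
        score += c * _log_or_neginf(1.0 - params.q_mod)
    if d:
        score += d * _log_or_neginf(params.q_mod / 2.0)
    return score


def apply_dmc_merge(g: LabeledGraph, keep: str, remove: str
                    ) -> tuple[LabeledGraph, list[tuple[str, str]]]:
    """Merge a duplicate pair: drop ``remove`` and give ``keep`` its links.

    Returns the predecessor graph (a copy) and the edges ``keep`` gained —
    the inferred ancestral edges of this step.
    """
    if keep == remove:
        raise ValueError("cannot merge a node with itself")
    if keep not in g or remove not in g:
        raise ValueError(f"nodes {keep!r}, {remove!r} must both be in the graph")
    out = g.copy()
    gained = [(keep, w) for w in sorted(out.neighbors(remove))
              if w != keep and not out.has_edge(keep, w)]
    out.remove_node(remove)
    out.add_edges_from(gained)
    return out, gained


def ff_anchor_likelihood(g: LabeledGraph, v: str, u: str, params: FFParams,
                         seed: int) -> float:
    """Simulation estimate of the likelihood that ``v`` most recently
    arrived by a fire anchored at ``u``.

    On the graph with ``v`` absent, runs ``params.n_sims`` fires from
    ``u`` and returns the fraction whose burned set equals
    ``N(v) \\ {u}``.  Asymmetric in ``(v, u)``; requires the edge.
    """
    if not g.has_edge(v, u):
        raise ValueError(f"({v!r}, {u!r}) must be an edge of the graph")
    labels = sorted(g.nodes)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n), dtype=np.uint8)
    for x, y in g.edges:
        a[index[x], index[y]] = 1
        a[index[y], index[x]] = 1
    active = np.ones(n, dtype=np.bool_)
    work = [np.empty(n, dtype=np.int64) for _ in range(4)]
    stamp = np.full(n, -1, dtype=np.int64)
    stream = _ff_kernel.candidate_seed(np.int64(seed) & 0x7FFFFFFF, index[v], index[u])
    return float(_ff_kernel.estimate_candidate(
        a, active, index[v], index[u], float(params.p),
        np.int64(params.n_sims), stream, stamp, work[0], work[1], work[2],
        work[3], np.int64(1)))


def pa_node_score(g: LabeledGraph, v: str) -> float:
    """PA removal score: sum of log predecessor-degrees of v's neighbors.

    Each neighbor ``u`` contributes ``log(deg(u) - 1)`` (its degree once
    ``v`` is gone).  Returns the minus-infinity sentinel when the score is
    undefined: ``v`` isolated, or some neighbor has degree 1.  The score
    does not depend on the attachment count ``m``.
    """
    if v not in g:
        raise ValueError(f"node {v!r} not in graph")
    degs = sorted(g.degree(u) for u in g.neighbors(v))
    if not degs or degs[0] <= 1:
        return NEG_INF
    # summing in sorted order makes equal degree-multisets give bit-equal
    # scores, so structural ties are detected exactly
    return float(sum(math.log(d - 1) for d in degs))


def total_log_likelihood(result: ReconstructionResult) -> float:
    """Sum of per-event log-likelihoods; minus infinity propagates."""
    return float(sum(e.log_likelihood for e in result.events))


# ---------------------------------------------------------------------------
# DMC score table (incremental)
# ---------------------------------------------------------------------------


def _count_term(counts: np.ndarray, logval: float) -> np.ndarray:
    """counts * logval with the 0 * (-inf) = 0 convention."""
    if np.isfinite(logval):
        return counts * logval
    return np.where(counts > 0, NEG_INF, 0.0)


class DMCScoreTable:
    """All-pairs DMC scores with dirty-set incremental maintenance.

    Scores are stored *without* the ``-log(N-1)`` factor (constant within
    a step, so it never affects the argmax); :meth:`score_of` adds it
    back.  After a merge, only pairs involving a node whose neighborhood
    changed — the kept node and the removed node's former neighbors — are
    recomputed, via a partial matrix product for the common-neighbor
    counts.  Entries for every other pair are provably unchanged.
    """

    def __init__(self, g: LabeledGraph, params: DMCParams):
        validate_graph(g)
        self.params = params
        self.labels = sorted(g.nodes)
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        self.a = np.zeros((n, n), dtype=np.float64)
        for x, y in g.edges:
            i, j = self.index[x], self.index[y]
            self.a[i, j] = 1.0
            self.a[j, i] = 1.0
        self.active = np.ones(n, dtype=bool)
        self.deg = self.a.sum(axis=1)
        self.cn = self.a @ self.a
        self.scores = np.full((n, n), NEG_INF)
        self._lg_con = _log_or_neginf(params.q_con)
        self._lg_ncon = _log_or_neginf(1.0 - params.q_con)
        self._lg_keep = _log_or_neginf(1.0 - params.q_mod)
        self._lg_half = _log_or_neginf(params.q_mod / 2.0)
        self._recompute_columns(np.arange(n))

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def _recompute_columns(self, cols: np.ndarray) -> None:
        a, deg, cn = self.a, self.deg, self.cn
        cn_cols = a @ a[:, cols]
        cn[:, cols] = cn_cols
        cn[cols, :] = cn_cols.T
        acols = a[:, cols]
        dcount = deg[:, None] + deg[None, cols] - 2.0 * acols - 2.0 * cn_cols
        s = np.where(acols > 0, self._lg_con, self._lg_ncon)
        s = s + _count_term(cn_cols, self._lg_keep)
        s = s + _count_term(dcount, self._lg_half)
        s[~self.active, :] = NEG_INF
        s[:, ~self.active[cols]] = NEG_INF
        s[cols, np.arange(len(cols))] = NEG_INF  # no self-pairs
        self.scores[:, cols] = s
        self.scores[cols, :] = s.T

    def score_of(self, u: str, v: str) -> float:
        """Current score of a pair, including the 1/(N-1) factor."""
        i, j = self.index[u], self.index[v]
        base = self.scores[i, j]
        if base == NEG_INF:
            return NEG_INF
        return float(base - math.log(self.n_active - 1))

    def as_dict(self) -> dict[frozenset, float]:
        """All active-pair scores (with the 1/(N-1) factor), for testing."""
        shift = math.log(self.n_active - 1)
        out = {}
        idx = np.flatnonzero(self.active)
        for ai, i in enumerate(idx):
            for j in idx[ai + 1:]:
                s = self.scores[i, j]
                out[frozenset((self.labels[i], self.labels[j]))] = (
                    NEG_INF if s == NEG_INF else float(s - shift))
        return out

    def best_pair(self, rng: np.random.Generator) -> tuple[int, int, float]:
        """Maximizing active pair; ties (including an all-sentinel table)
        broken uniformly at random.  Returns (i, j, full log-likelihood)."""
        smax = self.scores.max()
        if smax == NEG_INF:
            idx = np.flatnonzero(self.active)
            pairs = [(i, j) for ai, i in enumerate(idx) for j in idx[ai + 1:]]
            i, j = pairs[rng.integers(len(pairs))]
            return i, j, NEG_INF
        cand = np.argwhere(self.scores == smax)
        cand = cand[cand[:, 0] < cand[:, 1]]
        i, j = cand[rng.integers(len(cand))]
        return int(i), int(j), float(smax - math.log(self.n_active - 1))

    def merge(self, keep: int, remove: int) -> list[tuple[int, int]]:
        """Apply the predecessor construction; returns gained edge indices."""
        a = self.a
        old_neighbors = np.flatnonzero(a[remove] > 0)
        gained = [int(w) for w in old_neighbors
                  if w != keep and a[keep, w] == 0]
        a[remove, :] = 0.0
        a[:, remove] = 0.0
        for w in gained:
            a[keep, w] = 1.0
            a[w, keep] = 1.0
        self.active[remove] = False
        self.scores[remove, :] = NEG_INF
        self.scores[:, remove] = NEG_INF
        dirty = np.unique(np.append(old_neighbors, keep))
        dirty = dirty[dirty != remove]
        self.deg[dirty] = a[dirty].sum(axis=1)
        self.deg[remove] = 0.0
        if len(dirty):
            self._recompute_columns(dirty)
        return [(keep, w) for w in gained]


# ---------------------------------------------------------------------------
# Reversal engines
# ---------------------------------------------------------------------------


def _incident_edges(g: LabeledGraph, v: str) -> list[tuple[str, str]]:
    return [(v, w) for w in sorted(g.neighbors(v))]


def _reverse_dmc(g: LabeledGraph, params: DMCParams, rng: np.random.Generator,
                 snapshot_sizes: set[int], policy: str) -> ReconstructionResult:
    table = DMCScoreTable(g, params)
    labels = table.labels
    current = g.copy()
    events: list[ReverseEvent] = []
    ancestral: set[frozenset] = set()
    snapshots: dict[int, LabeledGraph] = {}
    n = len(labels)
    for _ in range(n - 1):
        if policy == "random":
            idx = np.flatnonzero(table.active)
            pairs = [(i, j) for ai, i in enumerate(idx) for j in idx[ai + 1:]]
            i, j = pairs[rng.integers(len(pairs))]
            s = table.scores[i, j]
            loglik = NEG_INF if s == NEG_INF else float(
                s - math.log(table.n_active - 1))
        else:
            i, j, loglik = table.best_pair(rng)
        keep, remove = (i, j) if rng.random() < 0.5 else (j, i)
        removed_label = labels[remove]
        kept_label = labels[keep]
        removed_edges = _incident_edges(current, removed_label)
        gained_idx = table.merge(keep, remove)
        gained = [(labels[x], labels[y]) for x, y in gained_idx]
        current.remove_node(removed_label)
        current.add_edges_from(gained)
        for e in gained:
            ancestral.add(frozenset(e))
        events.append(ReverseEvent(removed_label, kept_label, loglik,
                                   fallback=(loglik == NEG_INF),
                                   removed_edges=removed_edges,
                                   edges_added_to_predecessor=gained))
        if current.number_of_nodes() in snapshot_sizes:
            snapshots[current.number_of_nodes()] = current.copy()
    ancestral -= {frozenset(e) for e in g.edges}
    root = next(iter(current.nodes))
    return ReconstructionResult(events, root, "dmc",
                                {"q_mod": params.q_mod, "q_con": params.q_con},
                                ancestral, snapshots)


def _reverse_ff(g: LabeledGraph, params: FFParams, seed: int,
                snapshot_sizes: set[int]) -> ReconstructionResult:
    labels = sorted(g.nodes)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    a = np.zeros((n, n), dtype=np.uint8)
    for x, y in g.edges:
        a[index[x], index[y]] = 1
        a[index[y], index[x]] = 1
    ss = np.random.SeedSequence(seed)
    base_seed, tie_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    removed, anchors, estimates, fallback = _ff_kernel.ff_reverse_kernel(
        a, float(params.p), np.int64(params.n_sims),
        np.int64(base_seed), np.int64(tie_seed), True)
    current = g.copy()
    events: list[ReverseEvent] = []
    snapshots: dict[int, LabeledGraph] = {}
    for step in range(n - 1):
        v = labels[int(removed[step])]
        u = labels[int(anchors[step])]
        est = float(estimates[step])
        events.append(ReverseEvent(
            v, u, _log_or_neginf(est), fallback=bool(fallback[step]),
            removed_edges=_incident_edges(current, v)))
        current.remove_node(v)
        if current.number_of_nodes() in snapshot_sizes:
            snapshots[current.number_of_nodes()] = current.copy()
    root = next(iter(current.nodes))
    return ReconstructionResult(events, root, "ff", {"p": params.p},
                                set(), snapshots)


def _reverse_pa(g: LabeledGraph, rng: np.random.Generator,
                snapshot_sizes: set[int]) -> ReconstructionResult:
    current = g.copy()
    events: list[ReverseEvent] = []
    snapshots: dict[int, LabeledGraph] = {}
    n = current.number_of_nodes()
    for _ in range(n - 1):
        degrees = dict(current.degree())
        min_deg = min(degrees.values())
        candidates = sorted(v for v, d in degrees.items() if d == min_deg)
        scored = [(pa_node_score(current, v), v) for v in candidates]
        best = max(s for s, _ in scored)
        if best == NEG_INF:
            # every minimum-degree candidate is undefined: random whole-graph removal
            everyone = sorted(current.nodes)
            v = everyone[rng.integers(len(everyone))]
            loglik, is_fallback = NEG_INF, True
        else:
            ties = [v for s, v in scored if s == best]
            v = ties[rng.integers(len(ties))]
            loglik, is_fallback = best, False
        events.append(ReverseEvent(v, None, loglik, fallback=is_fallback,
                                   removed_edges=_incident_edges(current, v)))
        current.remove_node(v)
        if current.number_of_nodes() in snapshot_sizes:
            snapshots[current.number_of_nodes()] = current.copy()
    root = next(iter(current.nodes))
    return ReconstructionResult(events, root, "pa", {}, set(), snapshots)


def reverse(g: LabeledGraph, model: str,
            params: DMCParams | FFParams | PAParams | None,
            seed: int, snapshot_sizes=None,
            policy: str = "greedy") -> ReconstructionResult:
    """Greedily reverse ``g`` one growth step at a time until one node remains.

    Parameters
    ----------
    g : the extant network (undirected, simple, >= 2 nodes).
    model : ``"dmc"``, ``"ff"`` or ``"pa"``.
    params : model parameters (ignored for PA; its score is parameter-free).
    seed : RNG seed controlling tie-breaking, the DMC keep/remove coin and
        the FF simulation substreams.  Same inputs, same result.
    snapshot_sizes : optional node counts at which to store ancestral
        snapshots.
    policy : ``"greedy"`` (default) or, for DMC only, ``"random"`` — merge
        uniformly random pairs while still recording their model scores
        (the null reconstruction used for likelihood-ratio comparisons).
    """
    validate_graph(g)
    if g.number_of_nodes() < 2:
        raise ValueError("reversal needs a graph with at least 2 nodes")
    sizes = set(snapshot_sizes or ())
    if policy not in ("greedy", "random"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "random" and model != "dmc":
        raise ValueError("the random-merge null policy is implemented for DMC only")
    rng = np.random.default_rng(seed)
    if model == "dmc":
        if not isinstance(params, DMCParams):
            raise TypeError("DMC reversal needs DMCParams")
        return _reverse_dmc(g, params, rng, sizes, policy)
    if model == "ff":
        if not isinstance(params, FFParams):
            raise TypeError("FF reversal needs FFParams")
        return _reverse_ff(g, params, seed, sizes)
    if model == "pa":
        return _reverse_pa(g, rng, sizes)
    raise ValueError(f"unknown model {model!r}")
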