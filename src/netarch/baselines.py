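"""Heuristic, model-free node-age orderings used as comparators.

Both heuristics order node removals from static properties of the extant
graph: degree (remove low-degree nodes first, i.e. call them youngest) and
closeness centrality (remove the most central first).  They produce no
anchors and no likelihoods; they exist to show what a likelihood-based
reversal adds beyond "degree correlates with age".
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graph_core import LabeledGraph

__all__ = ["degree_order", "centrality_order"]


def _removal_to_arrival(removal: list[str]) -> list[str]:
    return list(reversed(removal))


def _sorted_removal(keys: dict[str, float], rng: np.random.Generator) -> list[str]:
    """Sort by key ascending; ties shuffled uniformly at random."""
    nodes = sorted(keys)
    jitter = rng.permutation(len(nodes))
    order = sorted(range(len(nodes)), key=lambda i: (keys[nodes[i]], jitter[i]))
    return [nodes[i] for i in order]


def degree_order(g: LabeledGraph, seed: int) -> list[str]:
    """Arrival order implied by static degree (hubs oldest).

    Removal proceeds in increasing extant degree with random tie-breaking;
    the returned list is the corresponding arrival order, oldest first.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(seed)
    removal = _sorted_removal({v: float(d) for v, d in g.degree()}, rng)
    return _removal_to_arrival(removal)


def centrality_order(g: LabeledGraph, seed: int) -> list[str]:
    """Arrival order implied by closeness centrality (most central removed
    first, hence youngest).

    On disconnected graphs networkx's Wasserman-Faust rescaling applies:
    within-component closeness scaled by (component size - 1)/(n - 1).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(seed)
    cc = nx.closeness_centrality(g, wf_improved=True)
    # decreasing centrality removal == ascending (-centrality)
    removal = _sorted_removal({v: -float(c) for v, c in cc.items()}, rng)
    return _removal_to_arrival(removal)
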