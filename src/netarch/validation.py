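"""Reconstruction-quality measures.

Rank agreement between true and inferred node arrival orders is measured
with Kendall's tau and the normalized Spearman footrule (1 for identical
orders; a random order scores 0.00 and 0.33 respectively in expectation).
Node/anchor history is compared via anchor trees: the percentage of the
true tree's clades recovered in the reconstructed tree, a close relative
of the Robinson-Foulds distance.  Annotation-based measures (age-class
Kendall, shared-annotation fractions for anchor pairs and for dated edges)
support validation on real networks where true arrival times are unknown
but node age classes or functional labels are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import AnchorTree, LabeledGraph, ReconstructionResult, clades

__all__ = [
    "kendall_tau",
    "footrule",
    "anchor_similarity",
    "class_kendall",
    "restrict_order",
    "anchor_pair_annotation_agreement",
    "edge_arrival_stamps",
    "edge_arrival_summary",
    "network_stats",
    "NetworkStats",
    "EdgeArrivalSummary",
]


def _positions(order: list[str]) -> dict[str, int]:
    pos = {v: i + 1 for i, v in enumerate(order)}  # 1-based arrival ranks
    if len(pos) != len(order):
        raise ValueError("order contains duplicate labels")
    return pos


def _paired_ranks(truth: list[str], predicted: list[str]) -> tuple[np.ndarray, np.ndarray]:
    pt, pp = _positions(truth), _positions(predicted)
    if set(pt) != set(pp):
        raise ValueError("orders must cover the same node set")
    nodes = sorted(pt)
    return (np.array([pt[v] for v in nodes]), np.array([pp[v] for v in nodes]))


def kendall_tau(truth: list[str], predicted: list[str]) -> float:
    """Kendall's tau between two total arrival orders, in [-1, 1].

    (concordant - discordant) / C(n, 2); 1 for identical, -1 for reversed.
    """
    a, b = _paired_ranks(truth, predicted)
    n = len(a)
    if n < 2:
        return 1.0
    # ranks are tie-free permutations, so the plain concordance formula is
    # exact (scipy's tau-b introduces float noise even on identical orders)
    i, j = np.triu_indices(n, 1)
    s = np.sign(a[i] - a[j]) * np.sign(b[i] - b[j])
    return float(s.sum()) / len(s)


def footrule(truth: list[str], predicted: list[str]) -> float:
    """Normalized Spearman footrule, in [0, 1].

    1 - sum_v |sigma(v) - sigma'(v)| / floor(n^2 / 2); 1 for identical
    orders, 0 for exactly opposite ones (even n).
    """
    a, b = _paired_ranks(truth, predicted)
    n = len(a)
    if n < 2:
        return 1.0
    f = float(np.abs(a - b).sum())
    return 1.0 - f / (n * n // 2)


def restrict_order(order: list[str], keep) -> list[str]:
    """Subsequence of ``order`` restricted to ``keep`` (relative order intact)."""
    keep = set(keep)
    return [v for v in order if v in keep]


def anchor_similarity(truth: AnchorTree, predicted: AnchorTree) -> float:
    """Percentage of the true tree's clades present in the predicted tree.

    Both trees must be over the same leaf set (restrict them first after
    node-deletion runs).  100 for identical trees; the root clade is
    always shared, so the floor for L leaves is 100/(L-1).
    """
    if truth.leaves() != predicted.leaves():
        raise ValueError("anchor trees must have identical leaf sets")
    ct = clades(truth)
    return 100.0 * len(ct & clades(predicted)) / len(ct)


def class_kendall(predicted: list[str], classes: dict[str, int]) -> float:
    """Kendall-style concordance over node pairs in different age classes.

    ``classes`` maps node label -> integer age class, larger = older.  A
    cross-class pair is correct when the node predicted to arrive earlier
    has the larger class; same-class pairs and unmapped nodes are ignored.
    """
    labeled = [v for v in predicted if v in classes]
    c = np.array([classes[v] for v in labeled])
    if len(np.unique(c)) < 2:
        raise ValueError("class-based Kendall needs at least two distinct classes")
    # pairs (i earlier than j): correct iff class_i > class_j
    diff = c[:, None] - c[None, :]
    upper = np.triu(np.ones_like(diff, dtype=bool), k=1)
    correct = int((diff[upper] > 0).sum())
    incorrect = int((diff[upper] < 0).sum())
    return (correct - incorrect) / (correct + incorrect)


@dataclass
class AnnotationAgreement:
    pair_fraction: float      # inferred node/anchor pairs sharing a label
    n_pairs: int              # testable pairs
    edge_baseline: float      # extant edges whose endpoints share a label


def anchor_pair_annotation_agreement(result: ReconstructionResult,
                                     labels: dict[str, set],
                                     g: LabeledGraph) -> AnnotationAgreement:
    """Fraction of inferred (node, anchor) pairs sharing an annotation.

    Pairs are testable when both members are extant and annotated.  The
    baseline is the fraction of extant edges whose endpoints share a
    label.
    """
    extant = set(g.nodes)
    shared = 0
    testable = 0
    for e in result.events:
        if e.anchor is None:
            continue
        if e.removed in extant and e.anchor in extant:
            la, lb = labels.get(e.removed), labels.get(e.anchor)
            if la and lb:
                testable += 1
                if la & lb:
                    shared += 1
    if testable == 0:
        raise ValueError("no testable annotated node/anchor pairs")
    base_num = base_den = 0
    for a, b in g.edges:
        la, lb = labels.get(a), labels.get(b)
        if la and lb:
            base_den += 1
            if la & lb:
                base_num += 1
    baseline = base_num / base_den if base_den else float("nan")
    return AnnotationAgreement(shared / testable, testable, baseline)


def edge_arrival_stamps(result: ReconstructionResult
                        ) -> tuple[dict[frozenset, int], LabeledGraph]:
    """Forward arrival step of every extant edge, by replaying the
    reconstruction forward.

    Step 0 is the root ancestor; step t adds the node removed at reverse
    step n-t.  An edge's stamp is the last forward step at which it
    (re)appears.  Returns (stamps over extant edges, the extant graph).
    """
    g = nx.Graph()
    g.add_node(result.root)
    stamps: dict[frozenset, int] = {}
    for t, ev in enumerate(reversed(result.events), start=1):
        # going forward, the edges the kept node gained in the ancestor vanish
        for e in ev.edges_added_to_predecessor:
            g.remove_edge(*e)
        g.add_node(ev.removed)
        for e in ev.removed_edges:
            g.add_edge(*e)
            stamps[frozenset(e)] = t
    extant_stamps = {e: t for e, t in stamps.items()
                     if g.has_edge(*tuple(e))}
    return extant_stamps, g


@dataclass
class EdgeArrivalSummary:
    newest_fraction: float      # newest-k extant edges joining same-label nodes
    oldest_fraction: float      # oldest-k extant edges, same
    extant_baseline: float      # all annotated extant edges, same
    ancestral_fraction: float   # inferred ancestral edges, same (nan if none)
    nonextant_baseline: float   # all annotated non-extant pairs, same


def edge_arrival_summary(result: ReconstructionResult,
                         labels: dict[str, set], k: int) -> EdgeArrivalSummary:
    """Shared-annotation fractions of the k newest / k oldest extant edges,
    with extant-edge and random-non-extant-pair baselines, plus the
    same-label fraction of inferred ancestral edges."""
    if not labels:
        raise ValueError("an annotation map is required")
    stamps, g = edge_arrival_stamps(result)
    annotated = [(e, t) for e, t in stamps.items()
                 if all(labels.get(v) for v in e)]
    if k > len(annotated):
        raise ValueError(f"k={k} exceeds the {len(annotated)} annotated extant edges")

    def share(edge: frozenset) -> bool:
        a, b = tuple(edge)
        return bool(labels[a] & labels[b])

    by_age = sorted(annotated, key=lambda et: et[1])
    oldest = by_age[:k]
    newest = by_age[-k:]
    extant_baseline = sum(share(e) for e, _ in annotated) / len(annotated)
    anc = [e for e in result.ancestral_edges if all(labels.get(v) for v in e)]
    anc_fraction = (sum(share(e) for e in anc) / len(anc)) if anc else float("nan")
    nodes = sorted(v for v in g.nodes if labels.get(v))
    non_num = non_den = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if not g.has_edge(a, b):
                non_den += 1
                if labels[a] & labels[b]:
                    non_num += 1
    nonextant_baseline = non_num / non_den if non_den else float("nan")
    return EdgeArrivalSummary(
        newest_fraction=sum(share(e) for e, _ in newest) / k,
        oldest_fraction=sum(share(e) for e, _ in oldest) / k,
        extant_baseline=extant_baseline,
        ancestral_fraction=anc_fraction,
        nonextant_baseline=nonextant_baseline,
    )


@dataclass
class NetworkStats:
    density: float
    clustering: float
    mean_shortest_path: float
    mean_core_number: float


def network_stats(g: LabeledGraph) -> NetworkStats:
    """Density, mean local clustering, mean shortest path length over
    connected pairs, and mean k-core number of a snapshot."""
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, dists in nx.shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    spl = total / pairs if pairs else float("nan")
    core = nx.core_number(g)
    return NetworkStats(
        density=float(nx.density(g)),
        clustering=float(nx.average_clustering(g)) if g.number_of_nodes() > 0 else 0.0,
        mean_shortest_path=spl,
        mean_core_number=float(np.mean(list(core.values()))),
    )
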